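"""End-to-end orchestration: corpus -> mixtures -> spectrograms ->
annotations -> (CutMix) -> training samples -> k-fold ensemble -> metrics.

Every stage is seeded from a single master seed (per-stage seeds are
derived deterministically), so a run directory is reconstructible from its
resolved config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotationSet,
    annotate_nonoverlap,
    annotate_overlap,
    species_box_stats,
    write_annotation_files,
)
from .augment import augment_dataset
from .detector import (
    Detection,
    TrainConfig,
    TrainingSample,
    decode,
    ensemble_predict,
    grouped_stratified_split,
    kfold_split,
    nms,
    train_fold,
)
from .evaluate import MetricsReport, evaluate_detections, threshold_sweep
from .fixtures import CallCorpus, gen_corpus, write_corpus
from .mixer import RenderedMixture, make_dataset, write_mixtures
from .model import DetectorNet, ModelConfig, build_model
from .spectro import Spectrogram, StftParams, downsample_mean, stft_spectrogram, to_db

__all__ = [
    "CorpusConfig",
    "MixtureConfig",
    "EvalConfig",
    "RunConfig",
    "class_map_for",
    "prepare_input",
    "mixtures_to_annotated",
    "annotated_to_samples",
    "train_ensemble",
    "predict_dataset",
    "run_pipeline",
    "end_to_end_nonoverlap",
    "train_and_evaluate_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class CorpusConfig:
    n_per_class: int = 24
    n_recordings_per_class: int = 6
    rate: int = 40_000


@dataclass
class MixtureConfig:
    mode: str = "nonoverlap"  # nonoverlap | overlap
    n_train: int = 300
    n_test: int = 100
    n_single_class: int = 0  # auxiliary single-class samples added to training
    window_s: float = 5.0
    snr_db: float = 4.0
    max_concurrency: int = 2


@dataclass
class EvalConfig:
    conf_threshold: float = 0.5
    sweep_thresholds: tuple[float, ...] = (0.2, 0.3, 0.4)
    iou_min: float = 0.5
    nms_overlap: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    mixtures: MixtureConfig = field(default_factory=MixtureConfig)
    stft: StftParams = field(default_factory=StftParams)
    cutmix_p: float = 0.5
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    save_audio: bool = True

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixtures"]["mode"] = self.mixtures.mode
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, prefix):
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - set(fields)
            if unknown:
                raise ValueError(f"unknown config field(s): {prefix}{sorted(unknown)}")
            kwargs = {}
            for name, f in fields.items():
                if name not in payload:
                    if (
                        f.default is dataclasses.MISSING
                        and f.default_factory is dataclasses.MISSING
                    ):
                        raise ValueError(f"missing config field: {prefix}{name}")
                    continue
                val = payload[name]
                if val is None:
                    raise ValueError(f"missing config field: {prefix}{name}")
                if dataclasses.is_dataclass(f.type) and isinstance(val, dict):
                    val = build(f.type, val, f"{prefix}{name}.")
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[name] = val
            return dc_type(**kwargs)

        # field types are strings under `from __future__ import annotations`;
        # resolve the nested dataclasses explicitly
        nested = {
            "corpus": CorpusConfig,
            "mixtures": MixtureConfig,
            "stft": StftParams,
            "model": ModelConfig,
            "train": TrainConfig,
            "eval": EvalConfig,
        }
        payload = dict(data or {})
        kwargs = {}
        for name, sub_type in nested.items():
            if name in payload:
                kwargs[name] = build(sub_type, payload.pop(name), f"{name}.")
        top = build(_TopLevel, payload, "")
        return cls(**{**vars(top), **kwargs})


@dataclass
class _TopLevel:
    seed: int = 0
    cutmix_p: float = 0.5
    save_audio: bool = True


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    h = np.random.SeedSequence([master, tag])
    return int(h.generate_state(1)[0] % (2**31))


def desk_scale_train_config(seed: int = 0) -> TrainConfig:
    """Training profile for CPU desk-scale runs.

    The full-scale defaults (300 epochs at learning rate 5e-4, five folds)
    assume GPU-day budgets; at a few hundred training mixtures on one CPU a
    shorter schedule with a proportionally higher learning rate and three
    folds reaches stable ensembles in minutes.
    """
    return TrainConfig(max_epochs=20, patience=10, folds=3, lr=6e-3, seed=seed)


# ---------------------------------------------------------------------------
# dataset preparation


def class_map_for(corpus: CallCorpus) -> dict[str, int]:
    return {name: i for i, name in enumerate(corpus.classes)}


def prepare_input(spec_db: Spectrogram, model_cfg: ModelConfig) -> np.ndarray:
    """Downsample a dB spectrogram to network geometry and rescale to ~[-1,1]."""
    x = downsample_mean(spec_db.values, model_cfg.input_bins, model_cfg.input_frames)
    return (x + 40.0) / 40.0


def mixtures_to_annotated(
    mixtures: list[RenderedMixture],
    stft: StftParams,
    class_map: dict[str, int],
    stats=None,
) -> list[tuple[Spectrogram, AnnotationSet]]:
    """STFT + dB conversion + automated annotation for a list of mixtures.

    Non-overlapping / single-class mixtures get measured (thresholded)
    boxes; overlap mixtures require ``stats`` (species mean box geometry).
    """
    out = []
    for mix in mixtures:
        spec = to_db(stft_spectrogram(mix.waveform, stft))
        if mix.manifest.mode == "overlap":
            if stats is None:
                raise ValueError("overlap annotation requires species box stats")
            ann = annotate_overlap(spec, mix.manifest, stats, class_map)
        else:
            ann = annotate_nonoverlap(spec, mix.manifest, class_map)
        out.append((spec, ann))
    return out


def annotated_to_samples(
    annotated: list[tuple[Spectrogram, AnnotationSet]], model_cfg: ModelConfig
) -> list[TrainingSample]:
    return [
        TrainingSample(
            x=prepare_input(spec, model_cfg),
            events=[(b.class_id, b.t_start_s, b.t_end_s) for b in ann.boxes],
            window_s=ann.window_s,
        )
        for spec, ann in annotated
    ]


# ---------------------------------------------------------------------------
# training / prediction


def train_ensemble(
    samples: list[TrainingSample],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[list[DetectorNet], list[list[dict]]]:
    """k-fold ensemble: each model validates on its own fold."""
    folds = kfold_split(len(samples), train_cfg.folds, train_cfg.seed)
    models, histories = [], []
    for fold in range(train_cfg.folds):
        train_s = [s for s, f in zip(samples, folds) if f != fold]
        val_s = [s for s, f in zip(samples, folds) if f == fold]
        model = build_model(model_cfg, seed=train_cfg.seed + fold)
        fold_cfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + 1000 + fold)
        model, hist = train_fold(model, train_s, val_s, fold_cfg)
        models.append(model)
        histories.append(hist)
        logger.info("fold %d finished after %d epochs", fold, len(hist))
    return models, histories


def predict_dataset(
    models: list[DetectorNet],
    samples: list[TrainingSample],
    eval_cfg: EvalConfig,
    raw_floor: float = 0.05,
) -> tuple[list[list[Detection]], list[list[Detection]]]:
    """Ensemble inference: (NMS-filtered at conf_threshold, raw at raw_floor)."""
    final, raw = [], []
    for s in samples:
        pmap = ensemble_predict(models, s.x, s.window_s)
        dets_raw = decode(pmap, raw_floor)
        raw.append(dets_raw)
        final.append(
            nms(
                [d for d in dets_raw if d.confidence >= eval_cfg.conf_threshold],
                eval_cfg.nms_overlap,
            )
        )
    return final, raw


# ---------------------------------------------------------------------------
# end-to-end runs


def _generate_datasets(cfg: RunConfig):
    """Corpus generation, grouped split, and train/test mixture rendering."""
    corpus = gen_corpus(
        cfg.corpus.n_per_class,
        cfg.corpus.n_recordings_per_class,
        cfg.corpus.rate,
        seed=_stage_seed(cfg.seed, "corpus"),
    )
    train_corpus, test_corpus = grouped_stratified_split(
        corpus, 0.6, seed=_stage_seed(cfg.seed, "split")
    )
    mc = cfg.mixtures
    common = dict(window_s=mc.window_s, snr_db=mc.snr_db, max_concurrency_cap=mc.max_concurrency)
    train_mixes = make_dataset(
        train_corpus, mc.n_train, mc.mode, _stage_seed(cfg.seed, "train_mix"), **common
    )
    if mc.n_single_class:
        train_mixes += make_dataset(
            train_corpus,
            mc.n_single_class,
            "single_class",
            _stage_seed(cfg.seed, "single_mix"),
            **common,
        )
    test_mixes = make_dataset(
        test_corpus, mc.n_test, mc.mode, _stage_seed(cfg.seed, "test_mix"), **common
    )
    return corpus, train_corpus, test_corpus, train_mixes, test_mixes


def _annotation_stats(train_corpus, cfg: RunConfig, cmap):
    """Species box stats measured on auxiliary non-overlapping mixtures."""
    ref = make_dataset(
        train_corpus,
        max(40, len(train_corpus.segments)),
        "nonoverlap",
        _stage_seed(cfg.seed, "stats_mix"),
        window_s=cfg.mixtures.window_s,
        snr_db=cfg.mixtures.snr_db,
    )
    annotated = mixtures_to_annotated(ref, cfg.stft, cmap)
    return species_box_stats([a for _, a in annotated], cmap)


def end_to_end_nonoverlap(cfg: RunConfig) -> tuple[MetricsReport, dict]:
    """Generate data, train, and evaluate on non-overlapping mixtures.

    Returns the metrics report at the configured confidence threshold plus
    a context dict with the artifacts (corpora, models, detections).
    """
    corpus, train_c, test_c, train_mixes, test_mixes = _generate_datasets(cfg)
    cmap = class_map_for(corpus)
    annotated_train = mixtures_to_annotated(train_mixes, cfg.stft, cmap)
    if cfg.cutmix_p > 0:
        annotated_train = augment_dataset(
            annotated_train, cfg.cutmix_p, _stage_seed(cfg.seed, "cutmix")
        )
    annotated_test = mixtures_to_annotated(test_mixes, cfg.stft, cmap)
    train_samples = annotated_to_samples(annotated_train, cfg.model)
    test_samples = annotated_to_samples(annotated_test, cfg.model)
    models, histories = train_ensemble(train_samples, cfg.model, cfg.train)
    final, raw = predict_dataset(models, test_samples, cfg.eval)
    gt = [[(c, t0, t1) for c, t0, t1 in s.events] for s in test_samples]
    rep = evaluate_detections(
        final, gt, cfg.eval.conf_threshold, classes=list(cmap.values())
    )
    ctx = {
        "corpus": corpus,
        "train_corpus": train_c,
        "test_corpus": test_c,
        "class_map": cmap,
        "models": models,
        "histories": histories,
        "train_mixes": train_mixes,
        "test_mixes": test_mixes,
        "annotated_train": annotated_train,
        "annotated_test": annotated_test,
        "detections": final,
        "raw_detections": raw,
        "ground_truth": gt,
    }
    return rep, ctx


def train_and_evaluate_overlap(
    train_corpus, test_corpus, cap: int, cfg: RunConfig, seed: int = 0
) -> MetricsReport:
    """Train and evaluate on overlap mixtures with a given concurrency cap."""
    mc = dataclasses.replace(cfg.mixtures, mode="overlap", max_concurrency=cap)
    local = dataclasses.replace(cfg, mixtures=mc, seed=cfg.seed + seed)
    cmap = {name: i for i, name in enumerate(train_corpus.classes)}
    stats = _annotation_stats(train_corpus, local, cmap)
    common = dict(window_s=mc.window_s, snr_db=mc.snr_db, max_concurrency_cap=cap)
    train_mixes = make_dataset(
        train_corpus, mc.n_train, "overlap", _stage_seed(local.seed, "train_mix"), **common
    )
    test_mixes = make_dataset(
        test_corpus, mc.n_test, "overlap", _stage_seed(local.seed, "test_mix"), **common
    )
    annotated_train = mixtures_to_annotated(train_mixes, local.stft, cmap, stats)
    if local.cutmix_p > 0:
        annotated_train = augment_dataset(
            annotated_train, local.cutmix_p, _stage_seed(local.seed, "cutmix")
        )
    annotated_test = mixtures_to_annotated(test_mixes, local.stft, cmap, stats)
    train_samples = annotated_to_samples(annotated_train, local.model)
    test_samples = annotated_to_samples(annotated_test, local.model)
    models, _ = train_ensemble(train_samples, local.model, local.train)
    final, _ = predict_dataset(models, test_samples, local.eval)
    gt = [[(c, t0, t1) for c, t0, t1 in s.events] for s in test_samples]
    return evaluate_detections(
        final, gt, local.eval.conf_threshold, classes=list(cmap.values())
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Full pipeline run writing all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("marinesed")
    root.addHandler(handler)
    try:
        cfg.save(out / "config.yaml")
        root.info("marinesed %s, master seed %d", __version__, cfg.seed)
        rep, ctx = end_to_end_nonoverlap(cfg)
        write_corpus(ctx["corpus"], out / "corpus")
        write_mixtures(ctx["train_mixes"], out / "mixtures_train", cfg.save_audio)
        write_mixtures(ctx["test_mixes"], out / "mixtures_test", cfg.save_audio)
        write_annotation_files(
            [(f"mix{i:05d}", ann) for i, (_, ann) in enumerate(ctx["annotated_train"])],
            out / "annotations_train",
            ctx["class_map"],
            image_width_frames=ctx["annotated_train"][0][0].n_frames,
            image_height_bins=ctx["annotated_train"][0][0].n_bins,
        )
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        for i, model in enumerate(ctx["models"]):
            np.savez(ckpt_dir / f"fold{i}.npz", **model.state_dict())
            root.info("fold %d trainable parameters: %d", i, model.n_params())
        loss_rows = [
            {"fold": f, **h} for f, hist in enumerate(ctx["histories"]) for h in hist
        ]
        pd.DataFrame(loss_rows).to_csv(out / "losses.csv", index=False)
        names = {v: k for k, v in ctx["class_map"].items()}
        rep.to_frame(names).to_csv(out / "metrics.csv", index=False)
        gt = ctx["ground_truth"]
        sweep = threshold_sweep(
            ctx["raw_detections"], gt, cfg.eval.sweep_thresholds, cfg.eval.nms_overlap
        )
        pd.concat([r.to_frame(names) for r in sweep.values()]).to_csv(
            out / "metrics_sweep.csv", index=False
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "macro": rep.macro,
                    "micro": rep.micro,
                    "threshold": rep.threshold,
                    "n_train": len(ctx["train_mixes"]),
                    "n_test": len(ctx["test_mixes"]),
                },
                fh,
                indent=1,
            )
        root.info("macro F %.3f micro F %.3f", rep.macro["f_score"], rep.micro["f_score"])
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
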