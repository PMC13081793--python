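"""Training and inference machinery for the temporal detector.

Covers the leakage-free grouped stratified corpus split, five-fold training
with AdamW and early stopping, target assignment and the composite loss
(objectness BCE everywhere + class BCE and temporal-IoU regression on
positive cells), elementwise prediction-map ensembling, confidence
decoding, and class-aware greedy non-maximum suppression.

Positive cells are those whose center time falls inside a ground-truth
event, assigned at the single scale whose cell width best matches the event
duration (anchor-free, one scale per event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fixtures import CallCorpus
from .model import DetectorNet, ModelConfig, PredictionMap
from . import nn
from .evaluate import temporal_iou

__all__ = [
    "TrainConfig",
    "TrainingSample",
    "Detection",
    "EarlyStopping",
    "TrainingError",
    "grouped_stratified_split",
    "kfold_split",
    "detection_loss",
    "train_fold",
    "average_maps",
    "ensemble_predict",
    "decode",
    "nms",
]

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (constant across folds)."""

    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 10
    lr: float = 5e-4
    weight_decay: float = 5e-4
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience, self.folds) < 1:
            raise ValueError("all TrainConfig integers must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainingSample:
    """One network input with its temporal ground truth.

    x: (input_bins, input_frames) normalized dB image.
    events: list of (class_id, t_start_s, t_end_s).
    """

    x: np.ndarray
    events: list[tuple[int, float, float]]
    window_s: float


@dataclass
class Detection:
    class_id: int
    t_start_s: float
    t_end_s: float
    confidence: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.t_start_s, self.t_end_s)


# ---------------------------------------------------------------------------
# data splits


def grouped_stratified_split(
    corpus: CallCorpus, train_fraction: float = 0.6, seed: int = 0
) -> tuple[CallCorpus, CallCorpus]:
    """Split a corpus ~train_fraction per class without splitting recordings.

    All segments of one recording land on the same side, eliminating
    within-recording leakage; within each class, whole recordings are
    assigned greedily (in seeded shuffled order) to the training side until
    its share reaches the target fraction.  A class with a single recording
    is assigned wholly to train with a warning.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for species in corpus.classes:
        idx = corpus.by_class(species)
        groups: dict[str, list[int]] = {}
        for i in idx:
            groups.setdefault(corpus.segments[i].recording_id, []).append(i)
        rec_ids = sorted(groups)
        if len(rec_ids) == 1:
            logger.warning(
                "class %s has a single recording; assigning it wholly to train",
                species,
            )
            train_idx.extend(idx)
            continue
        rng.shuffle(rec_ids)
        target = train_fraction * len(idx)
        count = 0
        for rid in rec_ids:
            size = len(groups[rid])
            # add the recording to train only if that moves the class's
            # train share closer to the target fraction
            if abs(count + size - target) <= abs(count - target):
                train_idx.extend(groups[rid])
                count += size
            else:
                test_idx.extend(groups[rid])
    return corpus.subset(sorted(train_idx)), corpus.subset(sorted(test_idx))


def kfold_split(n_samples: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each of n samples to one of k validation folds.

    Returns an int array of fold ids; folds partition the set and their
    sizes differ by at most one.
    """
    if k > n_samples:
        raise ValueError(f"k={k} exceeds number of samples {n_samples}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignment = np.empty(n_samples, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


# ---------------------------------------------------------------------------
# targets and loss

#: loss term weights: objectness, classification, box regression
LOSS_WEIGHTS = (1.0, 2.5, 2.0)
#: BCE weight given to positive objectness cells (negatives get 1)
POS_CELL_WEIGHT = 4.0


def _assign_scale(width_frames: float, strides: tuple[int, ...]) -> int:
    """Scale whose cell width best matches the event duration (log ratio)."""
    ratios = [abs(np.log(width_frames / s)) for s in strides]
    return int(np.argmin(ratios))


def build_targets(samples: list[TrainingSample], cfg: ModelConfig):
    """Per-scale objectness maps and positive-cell target arrays for a batch."""
    B = len(samples)
    cells = cfg.cells_per_scale
    obj = [np.zeros((B, 1, L)) for L in cells]
    pos: list[dict[str, list]] = [
        {"b": [], "l": [], "cls": [], "lo": [], "hi": []} for _ in cells
    ]
    for b, smp in enumerate(samples):
        frames_per_s = cfg.input_frames / smp.window_s
        for class_id, t0, t1 in smp.events:
            f0, f1 = t0 * frames_per_s, t1 * frames_per_s
            s = _assign_scale(max(f1 - f0, 1e-6), cfg.strides)
            stride, L = cfg.strides[s], cells[s]
            centers = (np.arange(L) + 0.5) * stride
            inside = np.flatnonzero((centers >= f0) & (centers <= f1))
            if inside.size == 0:  # very short event: nearest cell
                inside = np.array([int(np.clip((f0 + f1) / 2 / stride, 0, L - 1))])
            for l in inside:
                obj[s][b, 0, l] = 1.0
                pos[s]["b"].append(b)
                pos[s]["l"].append(int(l))
                pos[s]["cls"].append(class_id)
                pos[s]["lo"].append(f0)
                pos[s]["hi"].append(f1)
    return obj, pos


def detection_loss(
    raw_maps: list[nn.Tensor], samples: list[TrainingSample], cfg: ModelConfig
) -> nn.Tensor:
    """Composite detection loss over one batch."""
    obj_t, pos = build_targets(samples, cfg)
    w_obj, w_cls, w_box = LOSS_WEIGHTS
    terms: list[nn.Tensor] = []
    weights: list[float] = []
    for s, maps in enumerate(raw_maps):
        stride = cfg.strides[s]
        obj_logits = nn.slice_channels(maps, 0, 1)
        cell_weights = np.where(obj_t[s] > 0, POS_CELL_WEIGHT, 1.0)
        terms.append(nn.bce_logits_mean(obj_logits, obj_t[s], cell_weights))
        weights.append(w_obj)
        p = pos[s]
        if not p["b"]:
            continue
        bidx = np.asarray(p["b"])
        lidx = np.asarray(p["l"])
        gathered = nn.gather_bl(maps, bidx, lidx)  # (P, head_channels)
        cls_logits = nn.slice_channels(
            _as_bcl(gathered), 1, 1 + cfg.classes
        )
        n_pos = len(p["cls"])
        onehot = np.zeros((n_pos, cfg.classes, 1))
        onehot[np.arange(n_pos), p["cls"], 0] = 1.0
        terms.append(nn.bce_logits_mean(cls_logits, onehot))
        weights.append(w_cls)
        tx = _flatten(nn.slice_channels(_as_bcl(gathered), cfg.head_channels - 2, cfg.head_channels - 1))
        tw = _flatten(nn.slice_channels(_as_bcl(gathered), cfg.head_channels - 1, cfg.head_channels))
        cell_centers = (lidx + 0.5) * stride
        center = nn.addc(nn.mulc(nn.tanh(tx), cfg.offset_range_frames), cell_centers)
        width = nn.mulc(nn.exp(tw), float(stride))
        terms.append(nn.iou_loss_mean(center, width, np.asarray(p["lo"]), np.asarray(p["hi"])))
        weights.append(w_box)
    return nn.wsum(terms, weights)


def _as_bcl(gathered: nn.Tensor) -> nn.Tensor:
    """View a gathered (P, C) tensor as (P, C, 1) so channel ops apply."""
    p, c = gathered.data.shape
    out_data = gathered.data.reshape(p, c, 1)

    def backward(dy):
        if gathered.requires_grad:
            gathered._accumulate(dy.reshape(p, c))

    return nn.Tensor(out_data, parents=(gathered,), backward=backward)


def _flatten(x: nn.Tensor) -> nn.Tensor:
    shape = x.data.shape
    out_data = x.data.reshape(-1)

    def backward(dy):
        if x.requires_grad:
            x._accumulate(dy.reshape(shape))

    return nn.Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# training loop


class EarlyStopping:
    """Stop after `patience` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record a validation value; returns True when training should stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def _batch_x(samples: list[TrainingSample]) -> np.ndarray:
    return np.stack([s.x for s in samples])


def _eval_loss(model: DetectorNet, samples, cfg, batch_size: int) -> float:
    losses = []
    for i in range(0, len(samples), batch_size):
        batch = samples[i : i + batch_size]
        raw = model.forward(_batch_x(batch))
        losses.append(detection_loss(raw, batch, cfg).item() * len(batch))
    return float(np.sum(losses) / len(samples))


def train_fold(
    model: DetectorNet,
    train_samples: list[TrainingSample],
    val_samples: list[TrainingSample],
    tc: TrainConfig,
) -> tuple[DetectorNet, list[dict]]:
    """Train one model, restoring the best-validation-loss checkpoint.

    Returns the trained model and a per-epoch history of train/val losses.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    cfg = model.cfg
    opt = nn.AdamW(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    stopper = EarlyStopping(tc.patience)
    rng = np.random.default_rng(tc.seed)
    history: list[dict] = []
    best_state = model.state_dict()
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for i in range(0, len(order), tc.batch_size):
            batch = [train_samples[j] for j in order[i : i + tc.batch_size]]
            raw = model.forward(_batch_x(batch))
            loss = detection_loss(raw, batch, cfg)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss = _eval_loss(model, val_samples, cfg, tc.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_loss": val_loss}
        )
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_state = model.state_dict()
        logger.info(
            "epoch %d train %.4f val %.4f%s",
            epoch,
            history[-1]["train_loss"],
            val_loss,
            " *" if improved else "",
        )
        if stop:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, stopper.best_epoch)
            break
    model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# ensembling, decoding, NMS


def average_maps(maps: list[PredictionMap]) -> PredictionMap:
    """Elementwise arithmetic mean of prediction maps of identical geometry."""
    if not maps:
        raise ValueError("no prediction maps to average")
    geo = maps[0].geometry()
    for m in maps[1:]:
        if m.geometry() != geo:
            raise ValueError("prediction map geometry mismatch")
    n = len(maps)
    return PredictionMap(
        obj=[sum(m.obj[s] for m in maps) / n for s in range(len(geo) // 2)],
        cls=[sum(m.cls[s] for m in maps) / n for s in range(len(geo) // 2)],
        center_s=[sum(m.center_s[s] for m in maps) / n for s in range(len(geo) // 2)],
        width_s=[sum(m.width_s[s] for m in maps) / n for s in range(len(geo) // 2)],
        window_s=maps[0].window_s,
    )


def ensemble_predict(
    models: list[DetectorNet], x: np.ndarray, window_s: float
) -> PredictionMap:
    """Average the per-model prediction maps for one input elementwise."""
    return average_maps([m.predict(x, window_s) for m in models])


def decode(pmap: PredictionMap, conf_threshold: float) -> list[Detection]:
    """Cells with objectness x best-class score >= threshold become detections.

    Temporal bounds are clipped to [0, window_s].  Raising the threshold can
    only remove detections (monotone).
    """
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError("conf_threshold must be in [0, 1]")
    out: list[Detection] = []
    w = pmap.window_s
    for obj, cls, center, width in zip(pmap.obj, pmap.cls, pmap.center_s, pmap.width_s):
        best_cls = np.argmax(cls, axis=0)
        best_score = cls[best_cls, np.arange(cls.shape[1])]
        conf = obj * best_score
        for l in np.flatnonzero(conf >= conf_threshold):
            t0 = float(np.clip(center[l] - width[l] / 2.0, 0.0, w - 1e-6))
            t1 = float(np.clip(center[l] + width[l] / 2.0, t0 + 1e-6, w))
            out.append(Detection(int(best_cls[l]), t0, t1, float(conf[l])))
    return out


def nms(detections: list[Detection], overlap_threshold: float = 0.5) -> list[Detection]:
    """Greedy class-aware non-maximum suppression on temporal IoU.

    Detections are visited in descending confidence (ties broken by earlier
    start, then lower class id, so the result is order-independent); a
    detection is kept unless it overlaps an already kept detection of the
    same class with IoU > overlap_threshold.
    """
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, d.t_start_s, d.class_id)
    )
    kept: list[Detection] = []
    for d in ordered:
        if all(
            k.class_id != d.class_id
            or temporal_iou(d.interval, k.interval) <= overlap_threshold
            for k in kept
        ):
            kept.append(d)
    return kept
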