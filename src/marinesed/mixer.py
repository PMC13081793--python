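"""Synthetic monitoring-sample construction.

A monitoring sample is a fixed 5-s window emulating a passive acoustic
monitoring recording: call segments drawn from a corpus are placed on a
timeline (non-overlapping with small random gaps, overlapping under a
concurrency cap, or a single event), summed into a clean mixture, embedded
in Gaussian noise at a controlled signal-to-noise ratio

    20 * log10(RMS_clean / RMS_noise) = SNR_target   (dB),

and finally RMS-normalized to unit level.  Ground-truth event placements
are recorded in a manifest and drive annotation downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .fixtures import (
    CallCorpus,
    DegenerateInputError,
    Waveform,
    rms,
    rms_normalize,
    write_wav,
)

__all__ = [
    "EventPlacement",
    "MixtureManifest",
    "RenderedMixture",
    "PlanningError",
    "DEFAULT_WINDOW_S",
    "DEFAULT_SNR_DB",
    "plan_nonoverlap",
    "plan_overlap",
    "plan_single_class",
    "target_noise_rms",
    "render",
    "max_concurrency",
    "make_dataset",
    "write_mixtures",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 5.0
#: Default target SNR for noise injection, in dB.
DEFAULT_SNR_DB = 4.0
#: Range of the small random gaps inserted between non-overlapping events (s).
GAP_RANGE_S = (0.05, 0.3)
#: Default number of events per multi-event mixture (inclusive range).
N_EVENTS_RANGE = (2, 4)
_MAX_RETRIES = 100


class PlanningError(RuntimeError):
    """Raised when a mixture plan cannot satisfy its constraints."""


@dataclass
class EventPlacement:
    species: str
    segment_ref: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("need 0 <= start_s < end_s")


@dataclass
class MixtureManifest:
    """Planned event placements plus noise settings for one monitoring sample."""

    events: list[EventPlacement]
    window_s: float = DEFAULT_WINDOW_S
    snr_db: float = DEFAULT_SNR_DB
    mode: str = "nonoverlap"
    max_concurrency: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.end_s > self.window_s + 1e-9:
                raise ValueError("event extends beyond the window")


@dataclass
class RenderedMixture:
    """A rendered noisy monitoring waveform with its SNR bookkeeping.

    ``rms_clean`` and ``rms_noise`` are measured on the summed clean signal
    and the injected noise *before* the final normalization, so the realized
    SNR 20*log10(rms_clean/rms_noise) can always be audited after the fact.
    """

    waveform: Waveform
    manifest: MixtureManifest
    rms_clean: float
    rms_noise: float

    @property
    def realized_snr_db(self) -> float:
        return 20.0 * np.log10(self.rms_clean / self.rms_noise)


def max_concurrency(manifest: MixtureManifest) -> int:
    """Exact maximum number of events covering any instant (sweep line).

    Touching intervals ([0,1] and [1,2]) do not count as concurrent: ends
    are processed before starts at equal times.
    """
    if not manifest.events:
        return 0
    points: list[tuple[float, int]] = []
    for ev in manifest.events:
        points.append((ev.start_s, +1))
        points.append((ev.end_s, -1))
    points.sort(key=lambda p: (p[0], p[1]))  # -1 (end) sorts before +1 (start)
    best = cur = 0
    for _, delta in points:
        cur += delta
        best = max(best, cur)
    return best


def _pick_segments(
    corpus: CallCorpus, n_events: int, rng: np.random.Generator
) -> list[int]:
    """One randomly chosen segment from each of n distinct random classes."""
    classes = list(rng.choice(corpus.classes, size=n_events, replace=False))
    return [int(rng.choice(corpus.by_class(c))) for c in classes]


def plan_nonoverlap(
    corpus: CallCorpus,
    window_s: float = DEFAULT_WINDOW_S,
    n_events_range: tuple[int, int] = N_EVENTS_RANGE,
    rng_seed: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
) -> MixtureManifest:
    """Plan a mixture of temporally disjoint events from distinct classes.

    Events are laid out sequentially with small random gaps and a random
    global offset; if the drawn segments cannot fit in the window the plan
    retries with fewer events, failing only below two.
    """
    if len(corpus.classes) < 2:
        raise PlanningError("corpus must contain at least 2 classes")
    rng = np.random.default_rng(rng_seed)
    lo, hi = n_events_range
    n_events = int(rng.integers(lo, min(hi, len(corpus.classes)) + 1))
    while n_events >= 1:
        for _ in range(_MAX_RETRIES):
            refs = _pick_segments(corpus, n_events, rng)
            durs = [corpus.segments[r].duration for r in refs]
            gaps = rng.uniform(*GAP_RANGE_S, size=max(0, n_events - 1))
            total = sum(durs) + float(np.sum(gaps))
            if total > window_s:
                continue
            offset = rng.uniform(0.0, window_s - total)
            order = rng.permutation(n_events)
            events = []
            t = offset
            for k, idx in enumerate(order):
                r = refs[idx]
                events.append(
                    EventPlacement(
                        species=corpus.segments[r].species,
                        segment_ref=r,
                        start_s=t,
                        end_s=t + durs[idx],
                    )
                )
                t += durs[idx] + (gaps[k] if k < len(gaps) else 0.0)
            events.sort(key=lambda e: e.start_s)
            return MixtureManifest(
                events, window_s, snr_db, "nonoverlap", 1, rng_seed
            )
        if n_events <= 2:
            break
        n_events -= 1  # could not fit: retry with fewer events
    raise PlanningError("could not place even two non-overlapping events")


def plan_overlap(
    corpus: CallCorpus,
    window_s: float = DEFAULT_WINDOW_S,
    max_concurrency_cap: int = 2,
    n_events_range: tuple[int, int] = N_EVENTS_RANGE,
    rng_seed: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
) -> MixtureManifest:
    """Plan a mixture in which events genuinely overlap in time.

    Start times are drawn uniformly and the plan is accepted only if (a) the
    instantaneous concurrency never exceeds ``max_concurrency_cap`` and
    (b) at least one pair of events overlaps — otherwise an "overlap" sample
    could silently degenerate to a non-overlapping one.
    """
    if max_concurrency_cap < 2:
        raise ValueError("max_concurrency_cap must be >= 2")
    rng = np.random.default_rng(rng_seed)
    lo, hi = n_events_range
    n_events = int(rng.integers(max(2, lo), min(hi, len(corpus.classes)) + 1))
    for _ in range(_MAX_RETRIES):
        refs = _pick_segments(corpus, n_events, rng)
        events = []
        ok = True
        for r in refs:
            dur = corpus.segments[r].duration
            if dur > window_s:
                ok = False
                break
            start = rng.uniform(0.0, window_s - dur)
            events.append(
                EventPlacement(
                    species=corpus.segments[r].species,
                    segment_ref=r,
                    start_s=start,
                    end_s=start + dur,
                )
            )
        if not ok:
            continue
        manifest = MixtureManifest(
            sorted(events, key=lambda e: e.start_s),
            window_s,
            snr_db,
            "overlap",
            max_concurrency_cap,
            rng_seed,
        )
        if 2 <= max_concurrency(manifest) <= max_concurrency_cap:
            return manifest
    raise PlanningError(
        f"could not satisfy overlap constraints after {_MAX_RETRIES} tries"
    )


def plan_single_class(
    corpus: CallCorpus,
    window_s: float = DEFAULT_WINDOW_S,
    rng_seed: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
) -> MixtureManifest:
    """Plan a sample containing exactly one randomly placed event."""
    rng = np.random.default_rng(rng_seed)
    species = str(rng.choice(corpus.classes))
    ref = int(rng.choice(corpus.by_class(species)))
    dur = corpus.segments[ref].duration
    if dur > window_s:
        raise PlanningError("segment longer than the window")
    start = rng.uniform(0.0, window_s - dur)
    ev = EventPlacement(species, ref, start, start + dur)
    return MixtureManifest([ev], window_s, snr_db, "single_class", 1, rng_seed)


def target_noise_rms(rms_clean: float, snr_db: float) -> float:
    """Noise RMS achieving ``snr_db`` against a clean signal of ``rms_clean``."""
    if rms_clean <= 0:
        raise ValueError("rms_clean must be positive")
    return rms_clean / 10.0 ** (snr_db / 20.0)


def render(
    manifest: MixtureManifest, corpus: CallCorpus, rng_seed: int = 0
) -> RenderedMixture:
    """Render a manifest into a noisy, unit-RMS monitoring waveform.

    Zero-mean unit-variance Gaussian noise is drawn over the full window,
    rescaled so its RMS exactly matches the Eq.-style target, added to the
    summed clean mixture, and the result is RMS-normalized to 1.0.  The
    realized SNR is exact by construction and invariant under the final
    normalization.
    """
    rates = {corpus.segments[ev.segment_ref].rate for ev in manifest.events}
    if len(rates) != 1:
        raise ValueError("all referenced segments must share one rate")
    rate = rates.pop()
    n = int(round(manifest.window_s * rate))
    clean = np.zeros(n)
    for ev in manifest.events:
        seg = corpus.segments[ev.segment_ref]
        i0 = int(round(ev.start_s * rate))
        i1 = i0 + seg.samples.size
        if i1 > n + 1:
            raise ValueError("event placement falls outside the window")
        i1 = min(i1, n)
        clean[i0:i1] += seg.samples[: i1 - i0]
    rms_clean = float(np.sqrt(np.mean(clean**2)))
    if rms_clean == 0.0:
        raise DegenerateInputError("clean mixture is silent; cannot set SNR")
    rms_noise = target_noise_rms(rms_clean, manifest.snr_db)
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(n)
    noise *= rms_noise / np.sqrt(np.mean(noise**2))  # exact target RMS
    noisy = Waveform(clean + noise, rate)
    out = rms_normalize(noisy, 1.0)
    return RenderedMixture(out, manifest, rms_clean, rms_noise)


# ---------------------------------------------------------------------------
# Dataset assembly

_PLANNERS = {
    "nonoverlap": plan_nonoverlap,
    "overlap": plan_overlap,
    "single_class": plan_single_class,
}


def make_dataset(
    corpus: CallCorpus,
    n_samples: int,
    mode: str = "nonoverlap",
    seed: int = 0,
    window_s: float = DEFAULT_WINDOW_S,
    snr_db: float = DEFAULT_SNR_DB,
    max_concurrency_cap: int = 2,
) -> list[RenderedMixture]:
    """Plan and render ``n_samples`` mixtures of one mode.

    Per-sample seeds are derived deterministically from ``seed`` so the
    whole dataset is reproducible and samples are independent.
    """
    if mode not in _PLANNERS:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for i in range(n_samples):
        s = int(np.random.default_rng([seed, i]).integers(2**31))
        if mode == "nonoverlap":
            m = plan_nonoverlap(corpus, window_s, rng_seed=s, snr_db=snr_db)
        elif mode == "overlap":
            m = plan_overlap(
                corpus, window_s, max_concurrency_cap, rng_seed=s, snr_db=snr_db
            )
        else:
            m = plan_single_class(corpus, window_s, rng_seed=s, snr_db=snr_db)
        out.append(render(m, corpus, rng_seed=s + 1))
    return out


def write_mixtures(
    mixtures: list[RenderedMixture], out_dir: str | Path, save_audio: bool = True
) -> Path:
    """Write mixtures as WAV files plus a JSON-lines manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "mixtures.jsonl"
    with open(manifest_path, "w") as fh:
        for i, mix in enumerate(mixtures):
            name = f"mix{i:05d}.wav"
            if save_audio:
                write_wav(out / name, mix.waveform)
            rec = {
                "file": name,
                "mode": mix.manifest.mode,
                "window_s": mix.manifest.window_s,
                "snr_db": mix.manifest.snr_db,
                "seed": mix.manifest.seed,
                "rms_clean": mix.rms_clean,
                "rms_noise": mix.rms_noise,
                "events": [asdict(ev) for ev in mix.manifest.events],
            }
            fh.write(json.dumps(rec) + "\n")
    return manifest_path
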