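"""Automated bounding-box annotation on raw dB spectrogram matrices.

Core vocalizations stand out from background noise in magnitude, so boxes
can be derived without manual drawing: temporal bounds come straight from
the known event placements in the mixture manifest, and frequency bounds
are found by adaptive amplitude thresholding.  The background level is the
median of the dB matrix; the detection threshold sits the larger of 3 dB or
2.5 median-absolute-deviations above it; and a bidirectional search along
the frequency axis (downward from Nyquist and upward from 0 Hz) stops at
the first bin whose within-event mean magnitude exceeds the threshold.

For overlapping mixtures, mixed energy regions make per-event thresholding
unreliable, so each event instead receives its species' mean box height
(and mean center frequency), estimated from measured non-overlapping boxes.

Boxes serialize to YOLO text lines (``class x_center y_center width
height``, all normalized to [0, 1], image row 0 = Nyquist).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mixer import MixtureManifest
from .spectro import Spectrogram, time_to_frame

__all__ = [
    "BoundingBox",
    "AnnotationSet",
    "SpeciesBoxStats",
    "AnnotationFailure",
    "estimate_background",
    "adaptive_threshold",
    "freq_bounds",
    "annotate_nonoverlap",
    "species_box_stats",
    "annotate_overlap",
    "write_yolo",
    "read_yolo",
]

logger = logging.getLogger(__name__)


class AnnotationFailure(RuntimeError):
    """No frequency bin in the event window rises above the threshold."""


@dataclass
class BoundingBox:
    class_id: int
    t_start_s: float
    t_end_s: float
    f_low_hz: float
    f_high_hz: float
    source: str = "measured"  # or "species_mean"

    def __post_init__(self) -> None:
        if not self.t_start_s < self.t_end_s:
            raise ValueError("need t_start_s < t_end_s")
        if not (0 <= self.f_low_hz < self.f_high_hz):
            raise ValueError("need 0 <= f_low_hz < f_high_hz")

    @property
    def height_hz(self) -> float:
        return self.f_high_hz - self.f_low_hz

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.f_low_hz + self.f_high_hz)


@dataclass
class AnnotationSet:
    boxes: list[BoundingBox]
    window_s: float
    rate: int

    def __post_init__(self) -> None:
        nyq = self.rate / 2.0
        for b in self.boxes:
            if b.t_end_s > self.window_s + 1e-9 or b.f_high_hz > nyq + 1e-9:
                raise ValueError("box outside the window / Nyquist bounds")


@dataclass
class SpeciesBoxStats:
    """Per-class mean measured box geometry from non-overlapping samples."""

    mean_height_hz: dict[str, float]
    mean_center_hz: dict[str, float]
    counts: dict[str, int]


def estimate_background(s: Spectrogram) -> float:
    """Background noise level: median magnitude of the whole dB matrix."""
    if s.scale != "dB":
        raise ValueError("background estimation expects a dB spectrogram")
    if s.values.size == 0:
        raise ValueError("empty spectrogram")
    return float(np.median(s.values))


def adaptive_threshold(s: Spectrogram) -> float:
    """Detection threshold: background + max(3 dB, 2.5 * MAD).

    MAD is the median absolute deviation of the dB matrix about its median;
    both terms live on the dB scale so the max() is well defined.  Adding a
    constant to every cell shifts the threshold by that constant
    (translation equivariance), so the reference used for dB conversion is
    immaterial.
    """
    bg = estimate_background(s)
    mad = float(np.median(np.abs(s.values - bg)))
    return bg + max(3.0, 2.5 * mad)


def freq_bounds(
    s: Spectrogram, frame_start: int, frame_end: int, threshold: float
) -> tuple[int, int]:
    """Bidirectional frequency search inside one temporal window.

    For each bin, the mean magnitude over frames [frame_start, frame_end)
    is compared with ``threshold``; the search from 0 Hz upward gives the
    low bound, and from Nyquist downward the high bound.

    Raises
    ------
    AnnotationFailure
        If no bin in the window exceeds the threshold.
    """
    if not (0 <= frame_start < frame_end <= s.n_frames):
        raise ValueError("invalid frame window")
    profile = s.values[:, frame_start:frame_end].mean(axis=1)
    above = np.flatnonzero(profile > threshold)
    if above.size == 0:
        raise AnnotationFailure("no frequency bin exceeds the threshold")
    return int(above[0]), int(above[-1])


def _event_frames(ev, s: Spectrogram) -> tuple[int, int]:
    f0 = time_to_frame(ev.start_s, s.params, s.rate)
    f1 = time_to_frame(ev.end_s, s.params, s.rate)
    f0 = max(0, min(f0, s.n_frames - 1))
    f1 = max(f0 + 1, min(f1, s.n_frames))
    return f0, f1


def annotate_nonoverlap(
    s: Spectrogram, manifest: MixtureManifest, class_map: dict[str, int]
) -> AnnotationSet:
    """Measured boxes for a non-overlapping (or single-class) mixture.

    Temporal bounds are taken from the manifest verbatim; frequency bounds
    from the adaptive threshold search.  Events whose search fails are
    logged and omitted — never given fabricated full-band boxes.
    """
    if manifest.mode not in ("nonoverlap", "single_class"):
        raise ValueError("annotate_nonoverlap expects nonoverlap/single_class")
    thr = adaptive_threshold(s)
    boxes = []
    for ev in manifest.events:
        f0, f1 = _event_frames(ev, s)
        try:
            b_lo, b_hi = freq_bounds(s, f0, f1, thr)
        except AnnotationFailure:
            logger.warning(
                "annotation failure for %s event at %.2f-%.2f s; skipped",
                ev.species,
                ev.start_s,
                ev.end_s,
            )
            continue
        hz = s.rate / s.params.n_fft
        f_low = b_lo * hz
        f_high = min((b_hi + 1) * hz, s.nyquist)
        boxes.append(
            BoundingBox(
                class_id=class_map[ev.species],
                t_start_s=ev.start_s,
                t_end_s=ev.end_s,
                f_low_hz=f_low,
                f_high_hz=f_high,
                source="measured",
            )
        )
    return AnnotationSet(boxes, manifest.window_s, s.rate)


def species_box_stats(
    annotation_sets: list[AnnotationSet], class_map: dict[str, int]
) -> SpeciesBoxStats:
    """Mean measured box height and center frequency per class.

    Raises
    ------
    ValueError
        If any class in ``class_map`` has no measured box to average.
    """
    inv = {v: k for k, v in class_map.items()}
    heights: dict[str, list[float]] = {c: [] for c in class_map}
    centers: dict[str, list[float]] = {c: [] for c in class_map}
    for ann in annotation_sets:
        for b in ann.boxes:
            if b.source != "measured":
                continue
            sp = inv[b.class_id]
            heights[sp].append(b.height_hz)
            centers[sp].append(b.center_hz)
    empty = [c for c, h in heights.items() if not h]
    if empty:
        raise ValueError(f"no measured boxes for class(es): {empty}")
    return SpeciesBoxStats(
        mean_height_hz={c: float(np.mean(h)) for c, h in heights.items()},
        mean_center_hz={c: float(np.mean(v)) for c, v in centers.items()},
        counts={c: len(h) for c, h in heights.items()},
    )


def annotate_overlap(
    s: Spectrogram,
    manifest: MixtureManifest,
    stats: SpeciesBoxStats,
    class_map: dict[str, int],
) -> AnnotationSet:
    """Species-mean-height boxes for an overlapping mixture.

    Each event's frequency extent is its class mean center +- half the class
    mean height, truncated to [0, Nyquist]; temporal bounds come from the
    manifest.
    """
    if manifest.mode != "overlap":
        raise ValueError("annotate_overlap expects an overlap manifest")
    missing = {ev.species for ev in manifest.events} - set(stats.mean_height_hz)
    if missing:
        raise ValueError(f"missing species stats for: {missing}")
    nyq = s.nyquist
    boxes = []
    for ev in manifest.events:
        center = stats.mean_center_hz[ev.species]
        half = stats.mean_height_hz[ev.species] / 2.0
        f_low = max(0.0, center - half)
        f_high = min(nyq, center + half)
        boxes.append(
            BoundingBox(
                class_id=class_map[ev.species],
                t_start_s=ev.start_s,
                t_end_s=ev.end_s,
                f_low_hz=f_low,
                f_high_hz=f_high,
                source="species_mean",
            )
        )
    return AnnotationSet(boxes, manifest.window_s, s.rate)


# ---------------------------------------------------------------------------
# YOLO text serialization
#
# Image convention: x in frames left->right, y in bins with row 0 at Nyquist
# (top of a rendered spectrogram).  Coordinates are continuous and
# normalized by the image geometry, so write->read round-trips to within one
# frame/bin quantum.


def _box_to_pixels(b: BoundingBox, ann: AnnotationSet, w_frames: int, h_bins: int):
    x0 = b.t_start_s / ann.window_s * w_frames
    x1 = b.t_end_s / ann.window_s * w_frames
    nyq = ann.rate / 2.0
    # y grows downward from Nyquist
    y0 = (1.0 - b.f_high_hz / nyq) * h_bins
    y1 = (1.0 - b.f_low_hz / nyq) * h_bins
    return x0, x1, y0, y1


def write_yolo(ann: AnnotationSet, image_width_frames: int, image_height_bins: int) -> list[str]:
    """Serialize to YOLO lines ``class x_center y_center width height``."""
    lines = []
    for b in ann.boxes:
        x0, x1, y0, y1 = _box_to_pixels(b, ann, image_width_frames, image_height_bins)
        xc = (x0 + x1) / 2.0 / image_width_frames
        yc = (y0 + y1) / 2.0 / image_height_bins
        wn = (x1 - x0) / image_width_frames
        hn = (y1 - y0) / image_height_bins
        lines.append(f"{b.class_id} {xc:.6f} {yc:.6f} {wn:.6f} {hn:.6f}")
    return lines


def read_yolo(
    lines: list[str],
    window_s: float,
    rate: int,
    image_width_frames: int,
    image_height_bins: int,
) -> AnnotationSet:
    """Parse YOLO lines back into an AnnotationSet (inverse of write_yolo)."""
    nyq = rate / 2.0
    boxes = []
    for ln_no, raw in enumerate(lines, start=1):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split()
        if len(parts) != 5:
            raise ValueError(f"malformed YOLO line {ln_no}: {raw!r}")
        try:
            cid = int(parts[0])
            xc, yc, wn, hn = map(float, parts[1:])
        except ValueError as exc:
            raise ValueError(f"malformed YOLO line {ln_no}: {raw!r}") from exc
        t0 = (xc - wn / 2.0) * window_s
        t1 = (xc + wn / 2.0) * window_s
        f_high = (1.0 - (yc - hn / 2.0)) * nyq
        f_low = (1.0 - (yc + hn / 2.0)) * nyq
        boxes.append(
            BoundingBox(cid, max(0.0, t0), min(window_s, t1), max(0.0, f_low), min(nyq, f_high))
        )
    return AnnotationSet(boxes, window_s, rate)


def write_annotation_files(
    annotations: list[tuple[str, AnnotationSet]],
    out_dir: str | Path,
    class_map: dict[str, int],
    image_width_frames: int,
    image_height_bins: int,
) -> None:
    """Write one YOLO .txt per mixture plus class map and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "classes.txt", "w") as fh:
        for name, cid in sorted(class_map.items(), key=lambda kv: kv[1]):
            fh.write(f"{cid} {name}\n")
    sidecar = {}
    for stem, ann in annotations:
        with open(out / f"{stem}.txt", "w") as fh:
            fh.write("\n".join(write_yolo(ann, image_width_frames, image_height_bins)) + "\n")
        sidecar[stem] = [b.source for b in ann.boxes]
    with open(out / "sources.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
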