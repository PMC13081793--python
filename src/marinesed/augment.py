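"""Object-level CutMix for annotated spectrograms.

Unlike classic CutMix, the cut region is not random: it is an annotated
event's bounding-box rectangle, cropped from a donor spectrogram and pasted
(replacement semantics) into a base spectrogram at a uniformly drawn time
shift.  Vertical (frequency) shifts are deliberately forbidden — moving a
call out of its species' frequency band would create biologically
implausible training data — so the pasted rectangle occupies exactly the
donor's frequency rows.  The donor's label follows the patch as one
additional annotation; no label-area mixing is applied.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .annotate import AnnotationSet, BoundingBox
from .spectro import Spectrogram

__all__ = ["CutMixResult", "cutmix", "augment_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class CutMixResult:
    spectrogram: Spectrogram
    annotations: AnnotationSet
    donor_box: BoundingBox
    time_shift_frames: int


def _box_pixel_rect(
    box: BoundingBox, spec: Spectrogram, window_s: float
) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) of a box on the spectrogram grid (half-open)."""
    n_bins, n_frames = spec.values.shape
    nyq = spec.nyquist
    c0 = int(round(box.t_start_s / window_s * n_frames))
    c1 = int(round(box.t_end_s / window_s * n_frames))
    r0 = int(round(box.f_low_hz / nyq * n_bins))
    r1 = int(round(box.f_high_hz / nyq * n_bins))
    c1 = max(c0 + 1, min(c1, n_frames))
    r1 = max(r0 + 1, min(r1, n_bins))
    return r0, r1, c0, c1


def cutmix(
    base_spec: Spectrogram,
    base_ann: AnnotationSet,
    donor_spec: Spectrogram,
    donor_ann: AnnotationSet,
    rng_seed: int = 0,
) -> CutMixResult:
    """Paste one randomly chosen donor event into the base spectrogram.

    The donor rectangle keeps its frequency rows and is placed at a uniform
    random column offset such that it fits entirely inside the image.  Base
    values under the rectangle are replaced.  Inputs are never mutated.

    Note the paste may temporally overlap existing base events; that overlap
    exposure is the point of the augmentation and is not re-capped.
    """
    if base_spec.values.shape != donor_spec.values.shape:
        raise ValueError("base and donor spectrograms must share shape")
    if not donor_ann.boxes:
        raise ValueError("donor has no annotated events")
    rng = np.random.default_rng(rng_seed)
    donor_box = donor_ann.boxes[int(rng.integers(len(donor_ann.boxes)))]
    r0, r1, c0, c1 = _box_pixel_rect(donor_box, donor_spec, donor_ann.window_s)
    width = c1 - c0
    n_frames = base_spec.values.shape[1]
    if width > n_frames:
        raise ValueError("donor box wider than the image")
    new_c0 = int(rng.integers(0, n_frames - width + 1))
    shift = new_c0 - c0

    out_values = base_spec.values.copy()
    out_values[r0:r1, new_c0 : new_c0 + width] = donor_spec.values[r0:r1, c0:c1]
    out_spec = Spectrogram(out_values, base_spec.scale, base_spec.rate, base_spec.params)

    sec_per_frame = base_ann.window_s / n_frames
    new_box = BoundingBox(
        class_id=donor_box.class_id,
        t_start_s=new_c0 * sec_per_frame,
        t_end_s=(new_c0 + width) * sec_per_frame,
        f_low_hz=donor_box.f_low_hz,
        f_high_hz=donor_box.f_high_hz,
        source=donor_box.source,
    )
    out_ann = AnnotationSet(
        copy.deepcopy(base_ann.boxes) + [new_box], base_ann.window_s, base_ann.rate
    )
    return CutMixResult(out_spec, out_ann, donor_box, shift)


def augment_dataset(
    samples: list[tuple[Spectrogram, AnnotationSet]],
    p_apply: float = 0.5,
    rng_seed: int = 0,
) -> list[tuple[Spectrogram, AnnotationSet]]:
    """Independently CutMix-augment each training sample with prob p_apply.

    Donors are drawn (uniformly, excluding the base itself where possible)
    from the same sample list.  Intended for training data only; evaluation
    data must never pass through here.
    """
    if not (0.0 <= p_apply <= 1.0):
        raise ValueError("p_apply must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i, (spec, ann) in enumerate(samples):
        if p_apply > 0 and rng.random() < p_apply and len(samples) > 1:
            choices = [j for j in range(len(samples)) if j != i and samples[j][1].boxes]
            if choices:
                j = int(rng.choice(choices))
                seed = int(rng.integers(2**31))
                res = cutmix(spec, ann, samples[j][0], samples[j][1], rng_seed=seed)
                out.append((res.spectrogram, res.annotations))
                continue
        out.append((spec, ann))
    return out
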