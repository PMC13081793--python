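"""YOLO-style temporal detection network for spectrogram inputs.

The network follows the single-stage, anchor-free recipe adapted to purely
temporal event detection: a small convolutional backbone extracts features
at three temporal scales (strides 4, 8 and 16 along the frame axis), a
top-down (FPN) and bottom-up (PAN) fusion stage built from C2f blocks mixes
coarse context with fine resolution, and per-scale 1-D heads predict, for
every time cell, an objectness logit, per-class logits and temporal box
parameters (a tanh-bounded center offset and a log-width).  Frequency
content enters through the input representation — the dB spectrogram's
frequency bins are the input channels — so class identity is learned
implicitly while only start/end times are regressed, which suits calls
whose frequency bands are species-characteristic and stable.

A C2f block splits its input projection into a bypass branch and a branch
transformed by residual bottlenecks, then concatenates all branches and
fuses them with a 1x1 convolution (cross-stage-partial design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = ["ModelConfig", "PredictionMap", "C2f", "DetectorNet", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Geometry and capacity of the temporal detector.

    input_bins/input_frames: spectrogram geometry fed to the network (the
    raw STFT matrix is block-mean downsampled to this size).  channels: the
    per-scale fusion widths at strides (4, 8, 16).  offset_range_frames:
    maximum |center offset| a cell may predict, in input frames.
    """

    backbone: str = "small_cnn"
    input_bins: int = 96
    input_frames: int = 256
    stem_channels: int = 24
    channels: tuple[int, int, int] = (32, 48, 64)
    classes: int = 4
    strides: tuple[int, int, int] = (4, 8, 16)
    offset_range_frames: float = 64.0

    def __post_init__(self) -> None:
        if self.backbone != "small_cnn":
            raise ValueError(
                "only the 'small_cnn' backbone is available; pretrained "
                "image backbones require weight downloads"
            )
        if self.classes < 1:
            raise ValueError("classes must be >= 1")
        if len(self.channels) != 3 or len(self.strides) != 3:
            raise ValueError("exactly three feature scales are required")
        for s in self.strides:
            if self.input_frames % s:
                raise ValueError("input_frames must be divisible by each stride")

    @property
    def cells_per_scale(self) -> tuple[int, ...]:
        return tuple(self.input_frames // s for s in self.strides)

    @property
    def head_channels(self) -> int:
        # objectness + class logits + (center offset, log width)
        return 1 + self.classes + 2


@dataclass
class PredictionMap:
    """Decoded per-cell predictions for one input sample.

    Per scale: objectness probability, class probabilities, and box center /
    width in seconds.  Fixed geometry for a given ModelConfig, which is what
    makes elementwise ensemble averaging well defined.
    """

    obj: list[np.ndarray]  # each (L_s,)
    cls: list[np.ndarray]  # each (n_classes, L_s)
    center_s: list[np.ndarray]  # each (L_s,)
    width_s: list[np.ndarray]  # each (L_s,)
    window_s: float

    def geometry(self) -> tuple:
        return tuple(o.shape for o in self.obj) + tuple(c.shape for c in self.cls)


class Bottleneck(Module):
    def __init__(self, c: int, rng):
        self.cv1 = nn.ConvBlock(c, c, 3, rng=rng)
        self.cv2 = nn.ConvBlock(c, c, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.add(x, self.cv2(self.cv1(x)))


class C2f(Module):
    """Cross-stage-partial block with dual feature fusion.

    The input projection is split in half; one half bypasses processing
    while the other passes through ``n`` residual bottlenecks, every
    intermediate being kept; all branches are concatenated and fused by a
    1x1 convolution.  ``disable_bypass`` zeroes the bypass branch, degrading
    the block to the plain convolutional path (ablation hook).
    """

    def __init__(self, c_in: int, c_out: int, n: int = 1, rng=None):
        self.c_hidden = c_out // 2
        self.cv1 = nn.ConvBlock(c_in, 2 * self.c_hidden, 1, rng=rng)
        self.bottlenecks = [Bottleneck(self.c_hidden, rng) for _ in range(n)]
        self.cv2 = nn.ConvBlock((2 + n) * self.c_hidden, c_out, 1, rng=rng)
        self.disable_bypass = False

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        bypass = nn.slice_channels(y, 0, self.c_hidden)
        if self.disable_bypass:
            bypass = nn.mulc(bypass, 0.0)
        branch = nn.slice_channels(y, self.c_hidden, 2 * self.c_hidden)
        parts = [bypass, branch]
        for bn in self.bottlenecks:
            branch = bn(branch)
            parts.append(branch)
        return self.cv2(nn.concat(parts, axis=1))


class DetectorNet(Module):
    """Backbone -> FPN/PAN fusion -> three 1-D temporal detection heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        c0 = cfg.stem_channels
        c1, c2, c3 = cfg.channels
        # backbone: strides 2 -> 4 -> 8 -> 16 along time
        self.stem = nn.ConvBlock(cfg.input_bins, c0, 3, stride=2, rng=rng)
        self.down1 = nn.ConvBlock(c0, c1, 3, stride=2, rng=rng)
        self.c2f_p3 = C2f(c1, c1, rng=rng)
        self.down2 = nn.ConvBlock(c1, c2, 3, stride=2, rng=rng)
        self.c2f_p4 = C2f(c2, c2, rng=rng)
        self.down3 = nn.ConvBlock(c2, c3, 3, stride=2, rng=rng)
        self.c2f_p5 = C2f(c3, c3, rng=rng)
        # FPN (top-down)
        self.c2f_n4 = C2f(c3 + c2, c2, rng=rng)
        self.c2f_n3 = C2f(c2 + c1, c1, rng=rng)
        # PAN (bottom-up)
        self.pan_down3 = nn.ConvBlock(c1, c1, 3, stride=2, rng=rng)
        self.c2f_m4 = C2f(c1 + c2, c2, rng=rng)
        self.pan_down4 = nn.ConvBlock(c2, c2, 3, stride=2, rng=rng)
        self.c2f_m5 = C2f(c2 + c3, c3, rng=rng)
        # heads
        self.heads = [
            _Head(c, cfg.head_channels, rng) for c in (c1, c2, c3)
        ]

    def forward(self, x: np.ndarray) -> list[Tensor]:
        """x: (B, input_bins, input_frames) -> raw head maps per scale."""
        t = Tensor(x)
        p3 = self.c2f_p3(self.down1(self.stem(t)))
        p4 = self.c2f_p4(self.down2(p3))
        p5 = self.c2f_p5(self.down3(p4))
        n4 = self.c2f_n4(nn.concat([nn.upsample2(p5), p4], axis=1))
        n3 = self.c2f_n3(nn.concat([nn.upsample2(n4), p3], axis=1))
        m4 = self.c2f_m4(nn.concat([self.pan_down3(n3), n4], axis=1))
        m5 = self.c2f_m5(nn.concat([self.pan_down4(m4), p5], axis=1))
        return [h(f) for h, f in zip(self.heads, (n3, m4, m5))]

    def predict(self, x: np.ndarray, window_s: float) -> PredictionMap:
        """Run one sample (bins, frames) and decode raw maps to a PredictionMap."""
        cfg = self.cfg
        raw = self.forward(x[None])
        sec_per_frame = window_s / cfg.input_frames
        obj, cls, center_s, width_s = [], [], [], []
        for maps, stride in zip(raw, cfg.strides):
            m = maps.data[0]  # (head_channels, L)
            L = m.shape[1]
            obj.append(_sigmoid_np(m[0]))
            cls.append(_sigmoid_np(m[1 : 1 + cfg.classes]))
            cell_centers = (np.arange(L) + 0.5) * stride
            center = cell_centers + np.tanh(m[-2]) * cfg.offset_range_frames
            width = stride * np.exp(np.clip(m[-1], -8, 8))
            center_s.append(center * sec_per_frame)
            width_s.append(width * sec_per_frame)
        return PredictionMap(obj, cls, center_s, width_s, window_s)


class _Head(Module):
    def __init__(self, c_in: int, c_out: int, rng):
        self.block = nn.ConvBlock(c_in, c_in, 3, rng=rng)
        self.out = nn.Conv1d(c_in, c_out, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.block(x))


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def build_model(cfg: ModelConfig, seed: int = 0) -> DetectorNet:
    """Construct a detector with seeded (reproducible) initialization."""
    return DetectorNet(cfg, seed=seed)
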