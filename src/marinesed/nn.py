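"""Minimal reverse-mode autodiff on numpy arrays, sized for 1-D conv nets.

This engine provides exactly the primitives the temporal detector needs:
strided 1-D convolution, per-channel instance normalization, SiLU/tanh/exp,
concatenation and channel slicing, nearest-neighbour upsampling, batched
cell gathering, a numerically stable binary-cross-entropy-with-logits and a
temporal-IoU regression loss, plus an AdamW optimizer with decoupled weight
decay.  Gradients of every primitive are hand-derived and covered by finite
difference tests.

Tensors are float64 throughout: the networks are small enough that the
extra precision is free on CPU and makes gradient checks tight.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv1d",
    "ChannelNorm",
    "AdamW",
    "conv1d",
    "channel_norm",
    "silu",
    "tanh",
    "exp",
    "add",
    "addc",
    "mulc",
    "concat",
    "slice_channels",
    "upsample2",
    "gather_bl",
    "bce_logits_mean",
    "iou_loss_mean",
    "wsum",
]


class Tensor:
    """A numpy array plus the closure needed to backpropagate into parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: recursive parameter collection."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data = state[str(i)].copy()


# ---------------------------------------------------------------------------
# primitives


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Strided 1-D convolution: x (B,C,L), w (O,C,K), b (O,) -> (B,O,Lo)."""
    B, C, L = x.data.shape
    O, Cw, K = w.data.shape
    assert C == Cw, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lp = xp.shape[2]
    Lo = (Lp - K) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride][
        :, :, :Lo
    ]
    y = np.einsum("bclk,ock->bol", windows, w.data, optimize=True) + b.data[:, None]

    def backward(dy: np.ndarray) -> None:
        if w.requires_grad:
            w._accumulate(np.einsum("bclk,bol->ock", windows, dy, optimize=True))
        if b.requires_grad:
            b._accumulate(dy.sum(axis=(0, 2)))
        if x.requires_grad:
            G = np.einsum("bol,ock->bclk", dy, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            base = stride * np.arange(Lo)
            for k in range(K):  # indices unique for fixed k -> plain fancy add
                dxp[:, :, base + k] += G[:, :, :, k]
            x._accumulate(dxp[:, :, pad : pad + L] if pad else dxp)

    return Tensor(y, parents=(x, w, b), backward=backward)


def channel_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over time with affine params.

    y = gain * (x - mean)/sqrt(var + eps) + bias, statistics over the time
    axis for each (batch, channel).  Works identically in train and eval,
    with no running statistics, so inference is deterministic.
    """
    mu = x.data.mean(axis=2, keepdims=True)
    var = x.data.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gain.data * xhat + bias.data

    def backward(dy: np.ndarray) -> None:
        if gain.requires_grad:
            gain._accumulate((dy * xhat).sum(axis=(0, 2), keepdims=True))
        if bias.requires_grad:
            bias._accumulate(dy.sum(axis=(0, 2), keepdims=True))
        if x.requires_grad:
            dxhat = dy * gain.data
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=2, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor(y, parents=(x, gain, bias), backward=backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def silu(x: Tensor) -> Tensor:
    s = _sigmoid(x.data)
    y = x.data * s

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor(y, parents=(x,), backward=backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy * (1.0 - y**2))

    return Tensor(y, parents=(x,), backward=backward)


def exp(x: Tensor, clip: float = 8.0) -> Tensor:
    """Elementwise exp with input clipping for numerical safety."""
    z = np.clip(x.data, -clip, clip)
    y = np.exp(z)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            inside = (x.data >= -clip) & (x.data <= clip)
            x._accumulate(np.where(inside, dy * y, 0.0))

    return Tensor(y, parents=(x,), backward=backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    assert x.data.shape == y.data.shape
    out_data = x.data + y.data

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy)
        if y.requires_grad:
            y._accumulate(dy)

    return Tensor(out_data, parents=(x, y), backward=backward)


def addc(x: Tensor, const) -> Tensor:
    """Add a constant (ndarray or scalar, no gradient)."""
    c = np.asarray(const, dtype=np.float64)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy)

    return Tensor(x.data + c, parents=(x,), backward=backward)


def mulc(x: Tensor, const) -> Tensor:
    """Multiply by a constant (ndarray or scalar, no gradient)."""
    c = np.asarray(const, dtype=np.float64)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy * c)

    return Tensor(x.data * c, parents=(x,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(dy: np.ndarray) -> None:
        for t, o, s in zip(tensors, offsets[:-1], sizes):
            if t.requires_grad:
                sl = [slice(None)] * dy.ndim
                sl[axis] = slice(o, o + s)
                t._accumulate(dy[tuple(sl)])

    return Tensor(data, parents=tuple(tensors), backward=backward)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    data = x.data[:, start:stop]

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[:, start:stop] = dy
            x._accumulate(g)

    return Tensor(data, parents=(x,), backward=backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling along the time axis."""
    y = np.repeat(x.data, 2, axis=2)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy[:, :, 0::2] + dy[:, :, 1::2])

    return Tensor(y, parents=(x,), backward=backward)


def gather_bl(x: Tensor, bidx: np.ndarray, lidx: np.ndarray) -> Tensor:
    """Gather cells: x (B,C,L) at (bidx[p], :, lidx[p]) -> (P, C)."""
    bidx = np.asarray(bidx, dtype=np.intp)
    lidx = np.asarray(lidx, dtype=np.intp)
    data = x.data[bidx, :, lidx]

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, (bidx, slice(None), lidx), dy)
            x._accumulate(g)

    return Tensor(data, parents=(x,), backward=backward)


def bce_logits_mean(x: Tensor, target: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Weighted mean binary cross-entropy on logits (numerically stable)."""
    z = np.asarray(target, dtype=np.float64)
    w = np.ones_like(x.data) if weight is None else np.broadcast_to(
        np.asarray(weight, dtype=np.float64), x.data.shape
    )
    lx = x.data
    per = np.maximum(lx, 0) - lx * z + np.log1p(np.exp(-np.abs(lx)))
    wsum_ = w.sum()
    loss = (w * per).sum() / wsum_

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(dy * w * (_sigmoid(lx) - z) / wsum_)

    return Tensor(loss, parents=(x,), backward=backward)


def iou_loss_mean(
    c: Tensor, w: Tensor, gt_lo: np.ndarray, gt_hi: np.ndarray
) -> Tensor:
    """Temporal-IoU regression loss with a normalized center penalty.

    For predicted intervals [c - w/2, c + w/2] against ground truth
    [lo, hi]:  mean(1 - IoU + ((c - gc)/gl)^2), where gc/gl are the ground
    truth center and length.  The quadratic center term keeps a useful
    gradient even when prediction and target are disjoint.
    """
    lo = np.asarray(gt_lo, dtype=np.float64)
    hi = np.asarray(gt_hi, dtype=np.float64)
    cd, wd = c.data, np.maximum(w.data, 1e-9)
    l_p = cd - wd / 2.0
    r_p = cd + wd / 2.0
    inter = np.clip(np.minimum(r_p, hi) - np.maximum(l_p, lo), 0.0, None)
    union = wd + (hi - lo) - inter
    iou = inter / union
    gc = 0.5 * (lo + hi)
    gl = hi - lo
    center_term = ((cd - gc) / gl) ** 2
    n = cd.size
    loss = float(np.mean(1.0 - iou + center_term))

    right_free = r_p < hi  # moving the right edge changes the intersection
    left_free = l_p > lo
    active = inter > 0
    di_dc = (right_free.astype(float) - left_free.astype(float)) * active
    di_dw = 0.5 * (right_free.astype(float) + left_free.astype(float)) * active
    du_dc = -di_dc
    du_dw = 1.0 - di_dw
    diou_dc = (di_dc * union - inter * du_dc) / union**2
    diou_dw = (di_dw * union - inter * du_dw) / union**2

    def backward(dy: np.ndarray) -> None:
        if c.requires_grad:
            c._accumulate(dy * (-diou_dc + 2.0 * (cd - gc) / gl**2) / n)
        if w.requires_grad:
            w._accumulate(dy * (-diou_dw) / n)

    return Tensor(loss, parents=(c, w), backward=backward)


def wsum(tensors: Sequence[Tensor], weights: Sequence[float]) -> Tensor:
    """Weighted sum of scalar tensors."""
    data = sum(float(wt) * t.data for t, wt in zip(tensors, weights))

    def backward(dy: np.ndarray) -> None:
        for t, wt in zip(tensors, weights):
            if t.requires_grad:
                t._accumulate(dy * wt)

    return Tensor(data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# layers


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (c_in * k))  # He init for SiLU-ish gain
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, k)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ChannelNorm(Module):
    def __init__(self, c: int):
        self.g = Parameter(np.ones((1, c, 1)))
        self.b = Parameter(np.zeros((1, c, 1)))

    def __call__(self, x: Tensor) -> Tensor:
        return channel_norm(x, self.g, self.b)


class ConvBlock(Module):
    """Conv -> channel norm -> SiLU."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, rng=None):
        self.conv = Conv1d(c_in, c_out, k, stride, rng)
        self.norm = ChannelNorm(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return silu(self.norm(self.conv(x)))


class AdamW(Module):
    """Adam with decoupled weight decay (weight decay applied to the data,
    not folded into the moment estimates)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 5e-4,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
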