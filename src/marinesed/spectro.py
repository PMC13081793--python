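"""STFT magnitude spectrograms and time/frequency coordinate mappings.

The short-time Fourier transform used throughout is

    X[k, m] = sum_n x[n + mR] w[n] exp(-j 2 pi k n / N)

with window length N (default 1024 samples), hop R (default 256) and a
periodic Hann taper.  With center padding (reflect, N/2 each side) a signal
of L samples yields 1 + floor(L / R) frames and N/2 + 1 frequency bins on a
linear axis from 0 to Nyquist.  Magnitudes may be converted to dB relative
to the per-spectrogram maximum with a floor (default -80 dB).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

__all__ = [
    "StftParams",
    "Spectrogram",
    "stft_spectrogram",
    "to_db",
    "time_to_frame",
    "frame_to_time",
    "freq_to_bin",
    "bin_to_freq",
    "save_png",
]

DB_FLOOR = -80.0


@dataclass(frozen=True)
class StftParams:
    n_fft: int = 1024
    hop: int = 256
    window: str = "hann"
    center_pad: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.n_fft):
            raise ValueError("need 0 < hop <= n_fft")

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1


@dataclass
class Spectrogram:
    """Frequency-bin x frame magnitude matrix with its STFT provenance."""

    values: np.ndarray  # shape (n_bins, n_frames)
    scale: str  # "linear" or "dB"
    rate: int
    params: StftParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x frames)")
        if self.scale not in ("linear", "dB"):
            raise ValueError("scale must be 'linear' or 'dB'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.rate / self.params.n_fft

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.params.hop / self.rate


def stft_spectrogram(w, params: StftParams = StftParams()) -> Spectrogram:
    """Magnitude spectrogram |STFT| of a waveform.

    With ``center_pad`` the signal is reflect-padded by N/2 on both sides so
    frame m is centered on sample m*R; without it, frames cover the signal
    left-aligned and the input must be at least N samples long.
    """
    x = np.asarray(w.samples, dtype=np.float64)
    n_fft, hop = params.n_fft, params.hop
    if params.center_pad:
        x = np.pad(x, n_fft // 2, mode="reflect")
    elif x.size < n_fft:
        raise ValueError("signal shorter than n_fft and center_pad is off")
    n_frames = 1 + (x.size - n_fft) // hop
    frames = sliding_window_view(x, n_fft)[:: hop][:n_frames]
    win = get_window(params.window, n_fft, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T
    return Spectrogram(mag, "linear", w.rate, params)


def to_db(s: Spectrogram, floor_db: float = DB_FLOOR, ref: float | None = None) -> Spectrogram:
    """Convert a linear-magnitude spectrogram to dB re its maximum.

    Values are 20*log10(mag/ref) clipped below at ``floor_db``; zero
    magnitudes map to the floor rather than -inf.  The additive reference
    shift cancels out of any statistic computed on the same matrix (median,
    MAD), which is what the downstream annotation thresholding relies on.
    """
    if s.scale != "linear":
        raise ValueError("spectrogram is already dB-scaled")
    if ref is None:
        ref = float(s.values.max())
        if ref == 0.0:
            ref = 1.0  # all-silent input: everything lands on the floor
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(s.values / ref)
    db = np.maximum(db, floor_db)
    return Spectrogram(db, "dB", s.rate, s.params)


def time_to_frame(t: float, params: StftParams, rate: int) -> int:
    """Nearest STFT frame index for a time in seconds."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return int(round(t * rate / params.hop))


def frame_to_time(frame: int, params: StftParams, rate: int) -> float:
    """Time (s) at the center of an STFT frame (inverse of time_to_frame)."""
    return frame * params.hop / rate


def freq_to_bin(f_hz: float, params: StftParams, rate: int) -> int:
    """Nearest FFT bin index for a frequency in Hz."""
    return int(round(f_hz * params.n_fft / rate))


def bin_to_freq(bin_idx: int, params: StftParams, rate: int) -> float:
    return bin_idx * rate / params.n_fft


def downsample_mean(values: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Block-mean downsampling of a 2-D matrix to (out_rows, out_cols).

    Rows/columns are partitioned into nearly equal contiguous groups and
    averaged, which anti-aliases and is exactly reproducible.  Only
    downsampling is supported.
    """
    r, c = values.shape
    if out_rows > r or out_cols > c:
        raise ValueError("downsample_mean only reduces size")

    def _reduce(mat: np.ndarray, n_out: int) -> np.ndarray:
        edges = np.floor(np.linspace(0, mat.shape[0], n_out + 1)).astype(int)
        sums = np.add.reduceat(mat, edges[:-1], axis=0)
        counts = np.diff(edges)[:, None]
        return sums / counts

    return _reduce(_reduce(values, out_rows).T, out_cols).T


def save_png(s: Spectrogram, path, annotations=None) -> None:
    """Render a spectrogram (optionally with boxes) to PNG for inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    extent = (0, s.times[-1] if s.n_frames > 1 else 1.0, 0, s.nyquist)
    ax.imshow(s.values, origin="lower", aspect="auto", extent=extent, cmap="magma")
    if annotations is not None:
        for box in annotations.boxes:
            ax.add_patch(
                plt.Rectangle(
                    (box.t_start_s, box.f_low_hz),
                    box.t_end_s - box.t_start_s,
                    box.f_high_hz - box.f_low_hz,
                    fill=False,
                    edgecolor="cyan",
                )
            )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
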