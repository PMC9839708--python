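"""Segment → normalized two-channel spectrogram tensor.

Each 3-s window is converted by a short-time Fourier transform (window 256
samples, hop 128, Hann taper), optionally log-compressed as ``log(1 + |X|)``,
and z-scored twice: once along frequency rows, once along time columns.  The
two normalizations are stacked as channels, giving a ``[2, F, T]`` tensor
(channel 0 = row-normalized, channel 1 = column-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .synthetic import SegmentRecord

__all__ = ["SpectroConfig", "SpectrogramTensor", "stft_magnitude", "normalize_axis", "build_tensor"]


class SpectroError(ValueError):
    pass


@dataclass(frozen=True)
class SpectroConfig:
    window_size: int = 256
    hop: int = 128
    log_transform: bool = True
    eps: float = 1e-8


@dataclass
class SpectrogramTensor:
    """Normalized [2, F, T] time-frequency representation of one segment."""

    values: np.ndarray  # shape (2, F, T)
    window_size: int
    hop: int
    sampling_rate_hz: float
    segment_id: str = ""

    @property
    def n_freqs(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def frames(self) -> np.ndarray:
        """Frame sequence view for the recurrent model: shape (T, 2F).

        Frame t concatenates the frequency columns of both channels at time t.
        """
        return np.concatenate([self.values[0].T, self.values[1].T], axis=1)


def stft_magnitude(samples: np.ndarray, window_size: int = 256, hop: int = 128) -> np.ndarray:
    """One-sided STFT magnitude, frames at 0, hop, 2*hop, ...; trailing partial frame dropped.

    Returns an ``[F, T]`` matrix with ``F = window_size // 2 + 1`` and
    ``T = (L - window_size) // hop + 1``.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if hop < 1:
        raise SpectroError("hop must be >= 1")
    if samples.size < window_size:
        raise SpectroError(
            f"segment of {samples.size} samples is shorter than the {window_size}-sample window"
        )
    frames = sliding_window_view(samples, window_size)[::hop]
    win = get_window("hann", window_size, fftbins=True)
    return np.abs(np.fft.rfft(frames * win, axis=1)).T


def normalize_axis(matrix: np.ndarray, axis: str = "row", eps: float = 1e-8) -> np.ndarray:
    """Z-score each row or column (population std); slices with std <= eps map to zeros."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(matrix).all():
        raise SpectroError("non-finite values in spectrogram")
    if axis not in ("row", "column"):
        raise SpectroError(f"axis must be 'row' or 'column', got {axis!r}")
    ax = 1 if axis == "row" else 0
    mean = matrix.mean(axis=ax, keepdims=True)
    std = matrix.std(axis=ax, keepdims=True)
    out = np.where(std > eps, (matrix - mean) / np.where(std > eps, std, 1.0), 0.0)
    return out


def build_tensor(segment: SegmentRecord, config: SpectroConfig = SpectroConfig()) -> SpectrogramTensor:
    """STFT magnitude → optional log(1+m) → stacked row/column z-scores."""
    mag = stft_magnitude(segment.samples, config.window_size, config.hop)
    if config.log_transform:
        mag = np.log1p(mag)
    values = np.stack([
        normalize_axis(mag, "row", config.eps),
        normalize_axis(mag, "column", config.eps),
    ])
    return SpectrogramTensor(
        values=values,
        window_size=config.window_size,
        hop=config.hop,
        sampling_rate_hz=segment.sampling_rate_hz,
        segment_id=segment.segment_id,
    )
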