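"""Signal-to-spectrogram conversion.

Each channel of a raw window is turned into a fixed-size log-magnitude
time-frequency image: Hann-windowed STFT -> magnitude -> log(mag + eps) ->
bilinear resize to the target (H, W) -> per-channel min-max normalisation to
[0, 1].  Row 0 is the lowest frequency band; columns advance in time.

Resizing to a fixed (H, W) (default 48x48) is what makes the downstream
network independent of the raw signal length: a 80-sample window and a
6000-sample window both arrive as the same image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT, get_window
from skimage.transform import resize

__all__ = [
    "MultiChannelWindow",
    "SpectrogramStack",
    "StftParams",
    "default_segment_length",
    "stft_spectrogram",
    "convert_batch",
]

LOG_EPS = 1e-8  #: floor added to magnitudes before the log


@dataclass(frozen=True)
class MultiChannelWindow:
    """A raw fixed-rate signal window: C channels x L samples."""

    samples: np.ndarray
    sample_rate: float
    label: int | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError(f"samples must be 2-D (C, L), got shape {samples.shape}")
        c, length = samples.shape
        if c < 1 or length < 2:
            raise ValueError(f"need C >= 1 and L >= 2, got C={c}, L={length}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("window contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class SpectrogramStack:
    """C stacked log-magnitude spectrograms, each normalised to [0, 1]."""

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"values must be (C, H, W), got {v.shape}")
        if v.shape[1] < 2 or v.shape[2] < 2:
            raise ValueError("spectrogram must be at least 2x2")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StftParams:
    """STFT segmentation parameters; ``segment_length=None`` derives it from L."""

    segment_length: int | None = None
    hop: int | None = None
    window: str = "hann"
    log_eps: float = field(default=LOG_EPS)


def default_segment_length(n_samples: int) -> int:
    """L/8 rounded to the nearest power of two, at least 16, at most L."""
    target = max(n_samples / 8.0, 1.0)
    exponent = int(round(np.log2(target)))
    return int(min(max(2 ** exponent, 16), n_samples))


def _channel_spectrogram(x: np.ndarray, fs: float, params: StftParams):
    nperseg = params.segment_length or default_segment_length(x.size)
    if x.size < nperseg:
        raise ValueError(
            f"signal of length {x.size} shorter than one STFT segment ({nperseg})"
        )
    hop = params.hop or max(nperseg // 2, 1)
    win = get_window(params.window, nperseg)
    sft = ShortTimeFFT(win, hop=hop, fs=fs, mfft=nperseg, scale_to="magnitude")
    mag = np.abs(sft.stft(x))  # (freq_bins, frames), row 0 = DC
    log_mag = np.log(mag + params.log_eps)
    return log_mag, sft.f, sft.t(x.size)


def stft_spectrogram(window: MultiChannelWindow,
                     target_size: tuple[int, int] = (48, 48),
                     stft_params: StftParams | None = None) -> SpectrogramStack:
    """Convert one multi-channel window into a normalised spectrogram stack.

    Parameters
    ----------
    window:
        The raw C x L signal window.
    target_size:
        Output image size (H, W); every channel is resized to it.
    stft_params:
        Segmentation parameters; by default the segment length is derived
        from the window length (see :func:`default_segment_length`) with 50%
        overlap and a Hann window.
    """
    h, w = target_size
    if h < 2 or w < 2:
        raise ValueError(f"target size must be at least 2x2, got {target_size}")
    params = stft_params or StftParams()
    channels = []
    freqs = times = None
    for x in window.samples:
        log_mag, freqs, times = _channel_spectrogram(x, window.sample_rate, params)
        img = resize(log_mag, (h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        channels.append(img)
    freq_axis = np.linspace(freqs[0], freqs[-1], h)
    time_axis = np.linspace(times[0], times[-1], w)
    return SpectrogramStack(np.stack(channels), freq_axis, time_axis)


def convert_batch(windows: list[MultiChannelWindow],
                  target_size: tuple[int, int] = (48, 48),
                  stft_params: StftParams | None = None) -> list[SpectrogramStack]:
    """Order-preserving conversion of a batch of windows (all same C and rate)."""
    if not windows:
        return []
    c0, fs0 = windows[0].n_channels, windows[0].sample_rate
    for i, win in enumerate(windows):
        if win.n_channels != c0:
            raise ValueError(
                f"mixed channel counts in batch: window {i} has C={win.n_channels}, expected {c0}"
            )
        if win.sample_rate != fs0:
            raise ValueError(
                f"mixed sample rates in batch: window {i} has {win.sample_rate}, expected {fs0}"
            )
    return [stft_spectrogram(w, target_size, stft_params) for w in windows]
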