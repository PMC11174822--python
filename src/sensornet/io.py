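"""Reading and writing signal/spectrogram containers.

Two on-disk forms are supported:

* delimited text — one row per time sample, one column per channel, header
  row with channel names; a single window per file;
* an HDF5 container with datasets ``signals`` (N, C, L, float32) and
  ``labels`` (N, int) plus a ``sample_rate`` attribute.  Converted
  spectrograms use the same container with a ``spectrograms`` (N, C, H, W)
  dataset instead of ``signals``.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .spectrogram import MultiChannelWindow
from .training import SpectrogramDataset

__all__ = [
    "read_delimited_window",
    "write_signal_container",
    "read_signal_container",
    "write_spectrogram_container",
    "read_spectrogram_container",
]


def read_delimited_window(path, sample_rate: float,
                          label: int | None = None) -> MultiChannelWindow:
    """Read one window from a delimited text file (samples x channels)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 1 or frame.shape[0] < 2:
        raise ValueError(f"{path}: need at least one channel column and two rows")
    samples = frame.to_numpy(dtype=np.float64).T  # -> (C, L)
    return MultiChannelWindow(samples, sample_rate, label=label)


def write_signal_container(path, windows: list[MultiChannelWindow],
                           sample_rate: float | None = None) -> None:
    if not windows:
        raise ValueError("cannot write an empty container")
    fs = sample_rate if sample_rate is not None else windows[0].sample_rate
    signals = np.stack([w.samples for w in windows]).astype(np.float32)
    labels = np.array([-1 if w.label is None else w.label for w in windows],
                      dtype=np.int64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=signals)
        fh.create_dataset("labels", data=labels)
        fh.attrs["sample_rate"] = float(fs)


def read_signal_container(path) -> list[MultiChannelWindow]:
    with h5py.File(path, "r") as fh:
        if "signals" not in fh:
            raise ValueError(f"{path} has no 'signals' dataset")
        signals = fh["signals"][...]
        labels = fh["labels"][...] if "labels" in fh else np.full(len(signals), -1)
        fs = float(fh.attrs["sample_rate"])
    return [
        MultiChannelWindow(sig, fs, label=None if lbl < 0 else int(lbl))
        for sig, lbl in zip(signals, labels)
    ]


def write_spectrogram_container(path, dataset: SpectrogramDataset,
                                sample_rate: float) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("spectrograms", data=dataset.X.astype(np.float32))
        fh.create_dataset("labels", data=dataset.y)
        fh.attrs["sample_rate"] = float(sample_rate)


def read_spectrogram_container(path) -> SpectrogramDataset:
    with h5py.File(path, "r") as fh:
        if "spectrograms" not in fh:
            raise ValueError(f"{path} has no 'spectrograms' dataset")
        X = fh["spectrograms"][...]
        y = fh["labels"][...]
    return SpectrogramDataset(X, y)
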