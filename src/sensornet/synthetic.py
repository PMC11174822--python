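"""Seeded generator of labelled multi-channel signal windows.

Classes are mixtures of sinusoids: class k assigns a set of carrier
frequencies to each channel, so classes differ in time-frequency content —
both in where the energy sits and in how broadly it is spread (a narrow
"still"-like class, a harmonic "walk"-like class, a broadband "run"-like
class), which is how activity classes differ in real IMU spectrograms.
Channels of a window share a common random phase to the degree given by
``channel_coupling``, which gives cross-channel attention correlated
structure to exploit; white Gaussian noise is added on top.  Labels are
balanced exactly (round-robin) and everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectrogram import MultiChannelWindow

__all__ = ["ClassSpec", "SynthSpec", "generate", "make_transfer_pair"]


@dataclass(frozen=True)
class ClassSpec:
    """One class: carrier frequencies (Hz) per channel, and an amplitude.

    ``frequencies[c]`` is the tuple of carriers summed on channel c; a bare
    float is accepted and treated as a single carrier.
    """

    frequencies: tuple[tuple[float, ...], ...]
    amplitude: float = 1.0

    def __post_init__(self):
        freqs = tuple(
            (f,) if isinstance(f, (int, float)) else tuple(f)
            for f in self.frequencies
        )
        object.__setattr__(self, "frequencies", freqs)
        if any(len(f) == 0 for f in freqs):
            raise ValueError("every channel needs at least one carrier")


def _default_classes() -> tuple[ClassSpec, ...]:
    # narrow / harmonic / broadband spectral signatures on each channel
    return (
        ClassSpec(((3.0,), (4.0,), (5.0,))),
        ClassSpec(((8.0, 16.0), (9.0, 18.0), (10.0, 20.0))),
        ClassSpec(((6.0, 12.0, 18.0, 24.0),
                   (7.0, 14.0, 21.0, 28.0),
                   (5.5, 11.0, 16.5, 22.0))),
    )


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for a synthetic dataset.

    Defaults: 600 windows of 3 channels x 512 samples at 64 Hz, three
    sinusoid-mixture classes, phase coupling 0.7, noise sd 0.3.
    """

    n_windows: int = 600
    n_channels: int = 3
    n_samples: int = 512
    sample_rate: float = 64.0
    classes: tuple[ClassSpec, ...] = field(default_factory=_default_classes)
    channel_coupling: float = 0.7
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.channel_coupling <= 1.0:
            raise ValueError("channel_coupling must lie in [0, 1]")
        nyquist = self.sample_rate / 2.0
        for k, cls in enumerate(self.classes):
            if len(cls.frequencies) != self.n_channels:
                raise ValueError(
                    f"class {k} has carriers for {len(cls.frequencies)} channels, "
                    f"expected {self.n_channels}"
                )
            if any(f >= nyquist for chan in cls.frequencies for f in chan):
                raise ValueError(
                    f"class {k} has a carrier at or above Nyquist ({nyquist} Hz)"
                )

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def generate(spec: SynthSpec) -> list[MultiChannelWindow]:
    """Generate ``spec.n_windows`` labelled windows, classes round-robin."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sample_rate
    windows = []
    for idx in range(spec.n_windows):
        label = idx % spec.n_classes
        cls = spec.classes[label]
        samples = np.zeros((spec.n_channels, spec.n_samples))
        n_carriers = max(len(chan) for chan in cls.frequencies)
        for j in range(n_carriers):
            # one shared phase process per carrier slot, softened per channel
            shared_phase = rng.uniform(0, 2 * np.pi)
            own_phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
            phases = shared_phase + (1.0 - spec.channel_coupling) * own_phases
            for c, chan in enumerate(cls.frequencies):
                if j < len(chan):
                    samples[c] += cls.amplitude * np.sin(
                        2 * np.pi * chan[j] * t + phases[c]
                    )
        if spec.noise_sd > 0:
            samples += rng.normal(0.0, spec.noise_sd, size=samples.shape)
        windows.append(MultiChannelWindow(samples, spec.sample_rate, label=label))
    return windows


# Frequency palettes for the transfer experiment: a 4-channel source task and
# a 3-channel target task with disjoint carriers, mirroring pretraining on one
# sensor suite and fine-tuning on another.  Both keep the narrow / harmonic /
# broadband class structure of the defaults.
_SOURCE_CLASSES = (
    ClassSpec(((2.5,), (3.5,), (4.5,), (5.5,))),
    ClassSpec(((8.5, 17.0), (9.5, 19.0), (10.5, 21.0), (11.5, 23.0))),
    ClassSpec(((6.5, 13.0, 19.5, 26.0), (7.5, 15.0, 22.5, 30.0),
               (5.75, 11.5, 17.25, 23.0), (6.25, 12.5, 18.75, 25.0))),
)
_TARGET_CLASSES = (
    ClassSpec(((3.25,), (4.25,), (5.25,))),
    ClassSpec(((8.25, 16.5), (9.25, 18.5), (10.25, 20.5))),
    ClassSpec(((6.75, 13.5, 20.25, 27.0), (7.25, 14.5, 21.75, 29.0),
               (5.9, 11.8, 17.7, 23.6))),
)


def make_transfer_pair(seed: int = 0,
                       n_source: int = 600,
                       n_target: int = 200) -> tuple[SynthSpec, SynthSpec]:
    """Source (C=4) and target (C=3) dataset specs with disjoint palettes."""
    source = SynthSpec(n_windows=n_source, n_channels=4, classes=_SOURCE_CLASSES,
                       seed=seed)
    target = SynthSpec(n_windows=n_target, n_channels=3, classes=_TARGET_CLASSES,
                       seed=seed + 1)
    return source, target
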