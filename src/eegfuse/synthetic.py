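"""Synthetic band-limited EEG with class-conditional band-power effects.

Each recording is a pink-noise (1/f) background plus one random-phase
sinusoid bank per canonical band, per channel. A class effect multiplies
the amplitude of one band's component on a designated channel subset, so
an amplitude multiplier of ``m`` produces an ``m**2`` band-power ratio
against the null class on those channels.

The defaults emulate a 32-electrode, 128 Hz montage (which contains every
electrode of the C1/C2/C3 combinations) with 30 s recordings and a
gamma-band-only class effect: engagement (label +1) doubles and
neutrality (label 0) raises by 1.5x the gamma-band amplitude over the six
temporal C1 electrodes, while boredom (label -1) is the unmodified
background — a stylized version of the observation that high-frequency
temporal-lobe activity separates emotion classes. No physiological
artifacts (blinks, drifts, volume conduction) are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import BANDS, Recording, band_name

__all__ = [
    "BandEffect",
    "SyntheticSpec",
    "DEFAULT_MONTAGE_32",
    "generate_recording",
    "generate_dataset",
]

#: 32-label 10-20 montage containing all C1, C2 and C3 electrodes.
DEFAULT_MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C5", "C3", "Cz", "C4", "C6", "T8",
    "TP7", "CP5", "CP1", "CP2", "CP6", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

_C1_CHANNELS = ("FT7", "FT8", "T7", "T8", "TP7", "TP8")


@dataclass(frozen=True)
class BandEffect:
    """Amplitude multiplier applied to one band on a channel subset."""

    label: int
    band: str
    channels: tuple[str, ...]
    multiplier: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", band_name(self.band))
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def _default_effects() -> tuple[BandEffect, ...]:
    return (
        BandEffect(label=0, band="gamma", channels=_C1_CHANNELS, multiplier=1.5),
        BandEffect(label=1, band="gamma", channels=_C1_CHANNELS, multiplier=2.0),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Amplitudes are in arbitrary units (normalization removes scale);
    ``background_amp`` and ``band_amp`` are the standard deviations of the
    pink-noise background and of each band's oscillatory component.
    ``jitter`` is the relative per-recording amplitude noise.
    """

    n_subjects: int = 2
    recordings_per_class: int = 4
    duration_s: float = 30.0
    fs: float = 128.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE_32
    background_amp: float = 0.7
    band_amp: float = 0.7
    sinusoids_per_band: int = 8
    effects: tuple[BandEffect, ...] = field(default_factory=_default_effects)
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        montage_norm = {c.strip().upper() for c in self.montage}
        for eff in self.effects:
            missing = [c for c in eff.channels if c.strip().upper() not in montage_norm]
            if missing:
                raise ValueError(f"effect channels {missing} not in montage")
            if eff.label not in (-1, 0, 1):
                raise ValueError("effect label must be in {-1, 0, 1}")
        for b in BANDS.values():
            if b.f2 >= self.fs / 2:
                raise ValueError(
                    f"fs {self.fs} Hz too low for the {b.name} band "
                    f"(upper edge {b.f2} Hz)"
                )


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """Unit-std 1/f noise via spectral shaping with random phases."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_component(
    rng: np.random.Generator, n_channels: int, t: np.ndarray, f1: float, f2: float, k: int
) -> np.ndarray:
    """Unit-power sinusoid bank with random frequencies/phases in [f1, f2]."""
    freqs = rng.uniform(f1, f2, size=(n_channels, k))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, k))
    # amplitude sqrt(2/k) per sinusoid -> total variance 1 in expectation
    a = np.sqrt(2.0 / k)
    return a * np.sin(
        2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None]
    ).sum(axis=1)


def generate_recording(
    spec: SyntheticSpec, label: int, subject: int, index: int = 0
) -> Recording:
    """One labeled recording, deterministic per (seed, subject, label, index)."""
    if label not in (-1, 0, 1):
        raise ValueError("label must be in {-1, 0, 1}")
    seq = np.random.SeedSequence([spec.seed, subject, label + 1, index])
    rng = np.random.default_rng(seq)
    n = int(round(spec.duration_s * spec.fs))
    n_ch = len(spec.montage)
    t = np.arange(n) / spec.fs
    data = spec.background_amp * _pink_noise(rng, n_ch, n)
    montage_norm = [c.strip().upper() for c in spec.montage]
    for name, band in BANDS.items():
        comp = _band_component(
            rng, n_ch, t, band.f1, band.f2, spec.sinusoids_per_band
        )
        scale = np.full(n_ch, spec.band_amp)
        for eff in spec.effects:
            if eff.label == label and eff.band == name:
                idx = [montage_norm.index(c.strip().upper()) for c in eff.channels]
                scale[idx] *= eff.multiplier
        data += scale[:, None] * comp
    if spec.jitter > 0:
        data *= 1.0 + spec.jitter * rng.standard_normal()
    return Recording(
        data=data,
        fs=spec.fs,
        channels=spec.montage,
        label=label,
        subject_id=f"S{subject:02d}",
    )


def generate_dataset(
    spec: SyntheticSpec, labels: Sequence[int] = (-1, 0, 1)
) -> tuple[list[Recording], pd.DataFrame]:
    """Balanced labeled dataset plus a per-class manifest.

    Yields ``n_subjects * recordings_per_class`` recordings per class, in
    deterministic (subject, class, index) order.
    """
    if spec.n_subjects < 1 or spec.recordings_per_class < 1:
        raise ValueError("need at least one subject and one recording per class")
    recordings = []
    for subject in range(spec.n_subjects):
        for label in labels:
            for index in range(spec.recordings_per_class):
                recordings.append(generate_recording(spec, label, subject, index))
    manifest = (
        pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in recordings],
                "label": [r.label for r in recordings],
            }
        )
        .groupby("label")
        .size()
        .rename("n_recordings")
        .reset_index()
    )
    return recordings, manifest
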