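"""Frequency-band division and channel selection.

Turns raw multi-channel EEG recordings into model-ready per-band tensors:

1. zero-phase Butterworth band-pass decomposition into the five canonical
   bands (delta 1-4, theta 4-7, alpha 8-13, beta 13-30, gamma 31-50 Hz),
2. per-(subject, band, channel) z-scoring,
3. sliding-window segmentation (default 10 s windows, 2 s step),
4. selection of a named electrode combination (C1/C2/C3/All).

Filtering and normalization are applied to the full continuous recording
before windows are cut, so neighbouring windows share identical filter
state and statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Band",
    "BANDS",
    "BAND_ORDER",
    "Recording",
    "Segment",
    "ChannelCombination",
    "COMBINATIONS",
    "BandTensor",
    "FilterSpec",
    "RecordingTooShortError",
    "NyquistError",
    "FlatChannelError",
    "MissingChannelsError",
    "segment_recording",
    "segment_count",
    "design_bandpass",
    "decompose_bands",
    "normalize_band",
    "select_channels",
    "preprocess_dataset",
    "LABEL_TO_CLASS",
]


class RecordingTooShortError(ValueError):
    """Recording duration is below one analysis window."""


class NyquistError(ValueError):
    """Requested pass-band edge is at or above the Nyquist frequency."""


class FlatChannelError(ValueError):
    """A channel has zero variance and cannot be z-scored."""


class MissingChannelsError(KeyError):
    """A channel combination references electrodes absent from the montage."""


def _norm_label(label: str) -> str:
    return label.strip().upper()


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One canonical EEG frequency band with pass-band edges in Hz."""

    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"invalid band edges ({self.f1}, {self.f2})")


#: Canonical five-band decomposition used throughout the package.
BANDS: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 7.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 13.0, 30.0),
    "gamma": Band("gamma", 31.0, 50.0),
}

BAND_ORDER: tuple[str, ...] = tuple(BANDS)

_GREEK = {"δ": "delta", "θ": "theta", "α": "alpha", "β": "beta", "γ": "gamma"}


def band_name(name: str) -> str:
    """Normalize a band identifier (accepts greek letters and any case)."""
    key = _GREEK.get(name, name).strip().lower()
    if key not in BANDS:
        raise KeyError(f"unknown band {name!r}; expected one of {list(BANDS)}")
    return key


# ---------------------------------------------------------------------------
# Recordings and segments
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A continuous multi-channel EEG recording with one emotion label.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered 10-20 electrode labels, one per row of ``data``.
    label
        Emotion class in ``{-1, 0, 1}`` (boredom/negative, neutral,
        engagement/positive).
    subject_id
        Opaque subject identifier.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    label: int
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x time) array")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        normed = [_norm_label(c) for c in self.channels]
        if len(set(normed)) != len(normed):
            raise ValueError("duplicate channel labels in montage")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (-1, 0, 1):
            raise ValueError(f"label must be -1, 0 or 1; got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One analysis window, oriented time x channels."""

    data: np.ndarray
    start_s: float
    label: int


#: Mapping of raw emotion labels to contiguous class indices.
LABEL_TO_CLASS: dict[int, int] = {-1: 0, 0: 1, 1: 2}


def segment_count(n_samples: int, n_window: int, n_step: int) -> int:
    """Number of full sliding windows over ``n_samples`` samples.

    Trailing partial windows are dropped; the count is
    ``floor((n_samples - n_window) / n_step) + 1``.
    """
    if n_window <= 0 or n_step <= 0:
        raise ValueError("window and step must be positive")
    if n_samples < n_window:
        return 0
    return (n_samples - n_window) // n_step + 1


def segment_recording(
    recording: Recording, window_s: float = 10.0, step_s: float = 2.0
) -> list[Segment]:
    """Cut a recording into overlapping windows.

    Windows are measured in samples (``round(window_s * fs)``); segment *i*
    starts at sample ``i * round(step_s * fs)``. Every segment inherits the
    recording's label.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    n_window = int(round(window_s * recording.fs))
    n_step = int(round(step_s * recording.fs))
    if n_step < 1:
        raise ValueError("step_s is below one sample at this sampling rate")
    if recording.n_samples < n_window:
        raise RecordingTooShortError(
            f"recording of {recording.duration:.3f} s is shorter than the "
            f"{window_s:.3f} s analysis window"
        )
    n_seg = segment_count(recording.n_samples, n_window, n_step)
    out = []
    for i in range(n_seg):
        start = i * n_step
        out.append(
            Segment(
                data=recording.data[:, start : start + n_window].T.copy(),
                start_s=start / recording.fs,
                label=recording.label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """A designed Butterworth band-pass filter in cascaded-biquad form."""

    band: Band
    fs: float
    order: int
    sos: np.ndarray = field(repr=False)

    def magnitude(self, freqs: np.ndarray) -> np.ndarray:
        """Single-pass magnitude response at the given frequencies (Hz)."""
        _, h = sps.sosfreqz(self.sos, worN=np.asarray(freqs, float), fs=self.fs)
        return np.abs(h)


def design_bandpass(band: Band, fs: float, order: int = 4) -> FilterSpec:
    """Design an order-``order`` Butterworth band-pass filter.

    Realized as second-order sections for numerical stability. Raises
    :class:`NyquistError` when the upper edge reaches the Nyquist
    frequency (e.g. the gamma band at fs <= 100 Hz).
    """
    if band.f2 >= fs / 2:
        raise NyquistError(
            f"band {band.name} upper edge {band.f2} Hz is not below the "
            f"Nyquist frequency {fs / 2} Hz"
        )
    sos = sps.butter(order, (band.f1, band.f2), btype="bandpass", fs=fs, output="sos")
    return FilterSpec(band=band, fs=fs, order=order, sos=sos)


def decompose_bands(
    data: np.ndarray,
    fs: float,
    order: int = 4,
    bands: Mapping[str, Band] | None = None,
    skip_unresolvable: bool = False,
) -> dict[str, np.ndarray]:
    """Filter a (channels x time) matrix into the five canonical bands.

    Filtering is zero-phase (forward-backward second-order sections), so
    band outputs stay time-aligned with the input; the effective magnitude
    response is the square of the single-pass order-4 response.

    Parameters
    ----------
    skip_unresolvable
        If True, silently omit bands whose upper edge violates Nyquist
        (e.g. gamma at fs <= 100 Hz) instead of raising.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("input contains NaN or Inf samples")
    bands = dict(BANDS if bands is None else bands)
    out: dict[str, np.ndarray] = {}
    for name, band in bands.items():
        try:
            spec = design_bandpass(band, fs, order=order)
        except NyquistError:
            if skip_unresolvable:
                continue
            raise
        out[name] = sps.sosfiltfilt(spec.sos, data, axis=-1)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_band(
    data: np.ndarray,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    channels: Sequence[str] | None = None,
) -> np.ndarray:
    """Z-score a (channels x time) band signal per channel.

    Uses population (1/N) standard deviation. When ``stats`` is given it is
    a ``(mean, std)`` pair of per-channel arrays computed on a wider scope
    (e.g. the subject's full data); otherwise statistics come from ``data``
    itself.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < 2:
        raise ValueError("need more than one sample per channel to normalize")
    if stats is None:
        mean = data.mean(axis=-1)
        std = data.std(axis=-1)  # population (1/N)
    else:
        mean, std = (np.asarray(s, dtype=float) for s in stats)
    flat = np.flatnonzero(std == 0)
    if flat.size:
        names = (
            [channels[i] for i in flat]
            if channels is not None
            else [f"channel {i}" for i in flat]
        )
        raise FlatChannelError(f"zero-variance channel(s): {', '.join(map(str, names))}")
    return (data - mean[..., None]) / std[..., None]


# ---------------------------------------------------------------------------
# Channel combinations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelCombination:
    """A named ordered electrode subset."""

    name: str
    labels: tuple[str, ...]


#: Temporal-region electrode combinations. ``All`` keeps the montage order
#: of the data and is resolved at selection time.
COMBINATIONS: dict[str, ChannelCombination] = {
    "C1": ChannelCombination("C1", ("FT7", "FT8", "T7", "T8", "TP7", "TP8")),
    "C2": ChannelCombination(
        "C2",
        ("FT7", "T7", "TP7", "P7", "C5", "CP5", "FT8", "T8", "TP8", "P8", "C6", "CP6"),
    ),
    "C3": ChannelCombination("C3", ("T7", "P7", "CP5", "T8", "P8", "CP6")),
    "All": ChannelCombination("All", ()),
}


def _resolve_combo(combo: str | ChannelCombination) -> ChannelCombination:
    if isinstance(combo, ChannelCombination):
        return combo
    try:
        return COMBINATIONS[combo]
    except KeyError:
        raise KeyError(
            f"unknown channel combination {combo!r}; expected one of "
            f"{list(COMBINATIONS)}"
        ) from None


def combination_indices(
    montage: Sequence[str], combo: str | ChannelCombination
) -> np.ndarray:
    """Column indices of a combination's electrodes within a montage.

    Matching is case-insensitive and whitespace-stripped. ``All`` resolves
    to every montage channel in montage order.
    """
    combo = _resolve_combo(combo)
    lookup = {_norm_label(c): i for i, c in enumerate(montage)}
    if combo.name == "All" and not combo.labels:
        return np.arange(len(montage))
    missing = [lab for lab in combo.labels if _norm_label(lab) not in lookup]
    if missing:
        raise MissingChannelsError(
            f"montage lacks electrode(s) {missing} required by {combo.name}"
        )
    return np.array([lookup[_norm_label(lab)] for lab in combo.labels])


def select_channels(
    data: np.ndarray,
    montage: Sequence[str],
    combo: str | ChannelCombination,
    axis: int = -1,
) -> np.ndarray:
    """Select a combination's channels (in its declared order) from ``data``.

    ``axis`` is the channel axis (default last, matching time x channels
    segment orientation).
    """
    idx = combination_indices(montage, combo)
    return np.take(data, idx, axis=axis)


# ---------------------------------------------------------------------------
# Dataset-level preprocessing
# ---------------------------------------------------------------------------

@dataclass
class BandTensor:
    """Windowed, per-band, channel-selected dataset ready for the model.

    ``data`` maps each band name to an array of shape
    ``(n_segments, n_window, n_channels)``; rows are aligned with
    ``labels`` (class indices 0/1/2), ``subjects``, and ``groups``
    (source-recording index, for leakage-free grouped splits).
    """

    data: dict[str, np.ndarray]
    labels: np.ndarray
    subjects: np.ndarray
    channels: tuple[str, ...]
    fs: float
    window_s: float
    step_s: float
    manifest: pd.DataFrame
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.groups is None:
            # without provenance every segment is its own group
            self.groups = np.arange(self.labels.shape[0])

    @property
    def n_segments(self) -> int:
        return int(self.labels.shape[0])

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(self.data)

    def select_bands(self, bands: Iterable[str]) -> "BandTensor":
        names = [band_name(b) for b in bands]
        return BandTensor(
            data={b: self.data[b] for b in names},
            labels=self.labels,
            subjects=self.subjects,
            channels=self.channels,
            fs=self.fs,
            window_s=self.window_s,
            step_s=self.step_s,
            manifest=self.manifest,
            groups=self.groups,
        )

    def select_channels(self, combo: str | ChannelCombination) -> "BandTensor":
        idx = combination_indices(self.channels, combo)
        return BandTensor(
            data={b: a[:, :, idx] for b, a in self.data.items()},
            labels=self.labels,
            subjects=self.subjects,
            channels=tuple(self.channels[i] for i in idx),
            fs=self.fs,
            window_s=self.window_s,
            step_s=self.step_s,
            manifest=self.manifest,
            groups=self.groups,
        )

    def take(self, indices: np.ndarray) -> "BandTensor":
        """Row-subset (e.g. one cross-validation fold)."""
        indices = np.asarray(indices)
        return BandTensor(
            data={b: a[indices] for b, a in self.data.items()},
            labels=self.labels[indices],
            subjects=self.subjects[indices],
            channels=self.channels,
            fs=self.fs,
            window_s=self.window_s,
            step_s=self.step_s,
            manifest=self.manifest,
            groups=self.groups[indices],
        )

    def arrays(self, bands: Sequence[str] | None = None) -> dict[str, np.ndarray]:
        names = list(self.data) if bands is None else [band_name(b) for b in bands]
        return {b: self.data[b] for b in names}


def preprocess_dataset(
    recordings: Sequence[Recording],
    window_s: float = 10.0,
    step_s: float = 2.0,
    combo: str | ChannelCombination = "All",
    bands: Sequence[str] | None = None,
    stats_scope: str = "subject",
    order: int = 4,
    dtype=np.float32,
) -> BandTensor:
    """Run the full preprocessing chain over a set of recordings.

    Per recording: band decomposition (zero-phase), z-scoring, windowing,
    channel selection; segments are concatenated across recordings and raw
    labels {-1, 0, 1} are mapped to class indices {0, 1, 2}.

    ``stats_scope`` controls the normalization statistics:

    - ``"subject"`` (default): per (subject, band, channel), pooled over all
      of that subject's recordings — the widest scope, preserving relative
      band-power differences between a subject's recordings;
    - ``"recording"``: per (recording, band, channel);
    - ``"segment"``: per (segment, band, channel) after windowing.
    """
    if not recordings:
        raise ValueError("empty recording list")
    if stats_scope not in ("subject", "recording", "segment"):
        raise ValueError(f"unknown stats_scope {stats_scope!r}")
    fs = recordings[0].fs
    montage = tuple(_norm_label(c) for c in recordings[0].channels)
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("recordings have mixed sampling rates")
        if tuple(_norm_label(c) for c in rec.channels) != montage:
            raise ValueError("recordings have mixed montages")
    band_names = (
        list(BAND_ORDER) if bands is None else [band_name(b) for b in bands]
    )
    band_map = {b: BANDS[b] for b in band_names}
    idx = combination_indices(recordings[0].channels, combo)
    sel_channels = tuple(recordings[0].channels[i] for i in idx)

    # Filter everything once, grouped by subject so subject-scope statistics
    # can pool across that subject's recordings.
    by_subject: dict[str, list[int]] = {}
    for i, rec in enumerate(recordings):
        by_subject.setdefault(rec.subject_id, []).append(i)

    per_band_segments: dict[str, list[np.ndarray]] = {b: [] for b in band_names}
    labels: list[int] = []
    subjects: list[str] = []
    groups: list[int] = []
    manifest_rows = []

    for subject_id, rec_idx in by_subject.items():
        filtered = [
            decompose_bands(recordings[i].data, fs, order=order, bands=band_map)
            for i in rec_idx
        ]
        stats = None
        if stats_scope == "subject":
            stats = {}
            for b in band_names:
                cat = np.concatenate([f[b] for f in filtered], axis=-1)
                stats[b] = (cat.mean(axis=-1), cat.std(axis=-1))
        for f, i in zip(filtered, rec_idx):
            rec = recordings[i]
            n_seg = None
            for b in band_names:
                if stats_scope == "segment":
                    normed = f[b]
                else:
                    normed = normalize_band(
                        f[b],
                        stats=stats[b] if stats is not None else None,
                        channels=rec.channels,
                    )
                band_rec = Recording(
                    data=normed,
                    fs=fs,
                    channels=rec.channels,
                    label=rec.label,
                    subject_id=rec.subject_id,
                )
                segs = segment_recording(band_rec, window_s=window_s, step_s=step_s)
                arr = np.stack([s.data[:, idx] for s in segs]).astype(dtype)
                if stats_scope == "segment":
                    mean = arr.mean(axis=1, keepdims=True)
                    std = arr.std(axis=1, keepdims=True)
                    if np.any(std == 0):
                        raise FlatChannelError(
                            "zero-variance channel within a segment"
                        )
                    arr = (arr - mean) / std
                per_band_segments[b].append(arr)
                n_seg = arr.shape[0]
            labels.extend([LABEL_TO_CLASS[rec.label]] * n_seg)
            subjects.extend([rec.subject_id] * n_seg)
            groups.extend([i] * n_seg)  # source-recording index
            manifest_rows.append(
                {"subject_id": rec.subject_id, "n_segments": n_seg, "label": rec.label}
            )

    data = {b: np.concatenate(per_band_segments[b]) for b in band_names}
    return BandTensor(
        data=data,
        labels=np.array(labels, dtype=np.int64),
        subjects=np.array(subjects, dtype=object),
        channels=sel_channels,
        fs=fs,
        window_s=window_s,
        step_s=step_s,
        manifest=pd.DataFrame(manifest_rows),
        groups=np.array(groups, dtype=np.int64),
    )
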