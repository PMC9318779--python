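"""Readers, writers, metrics tables, and run manifests.

Two recording formats are supported:

- **EDF** — sampling rate and channel labels come from the header; the
  emotion label and subject id come from an optional JSON sidecar
  (``<stem>.json``) or keyword arguments.
- **matrix + sidecar** — a ``.npy`` or delimited-text matrix (rows = time,
  columns = channels for text; channels x time for ``.npy``) next to a
  JSON/YAML sidecar holding ``fs``, ``channels``, ``label`` and
  ``subject_id``.

Preprocessed tensors persist as an ``.npz`` container plus a plain-text
manifest (one row per recording: subject_id, n_segments, label).
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .preprocessing import BandTensor, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "save_tensor",
    "load_tensor",
    "write_metrics",
    "read_metrics",
    "RunManifest",
]

SIDECAR_KEYS = ("fs", "channels", "label", "subject_id")


class SidecarError(ValueError):
    """Sidecar metadata file is missing or incomplete."""


def _find_sidecar(path: Path) -> Path | None:
    for suffix in (".json", ".yaml", ".yml"):
        cand = path.with_suffix(suffix)
        if cand.exists() and cand != path:
            return cand
    return None


def _read_sidecar(path: Path) -> dict[str, Any]:
    text = path.read_text()
    meta = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(meta, dict):
        raise SidecarError(f"sidecar {path} does not contain a mapping")
    return meta


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    label: int | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a recording from EDF or a matrix + sidecar pair.

    ``fmt`` is inferred from the suffix when omitted (``.edf`` vs
    ``.npy``/``.csv``/``.tsv``/``.txt``). Explicit ``label``/``subject_id``
    arguments override sidecar values.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        return _read_edf(path, label=label, subject_id=subject_id)
    if fmt == "matrix":
        return _read_matrix(path, label=label, subject_id=subject_id)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edf(path: Path, label: int | None, subject_id: str | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    meta: dict[str, Any] = {}
    sidecar = _find_sidecar(path)
    if sidecar is not None:
        meta = _read_sidecar(sidecar)
    if label is None:
        label = meta.get("label")
    if label is None:
        raise SidecarError(
            f"no emotion label for {path}: pass label= or provide a sidecar"
        )
    data = raw.get_data(units="uV")
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        label=int(label),
        subject_id=str(subject_id or meta.get("subject_id", "S00")),
    )


def _read_matrix(path: Path, label: int | None, subject_id: str | None) -> Recording:
    sidecar = _find_sidecar(path)
    if sidecar is None:
        raise SidecarError(f"no sidecar metadata file found next to {path}")
    meta = _read_sidecar(sidecar)
    for key in ("fs", "channels"):
        if key not in meta:
            raise SidecarError(f"sidecar {sidecar} lacks required key {key!r}")
    if label is None:
        if "label" not in meta:
            raise SidecarError(f"sidecar {sidecar} lacks required key 'label'")
        label = meta["label"]
    if path.suffix == ".npy":
        data = np.load(path)  # channels x time
    else:
        sep = "\t" if path.suffix == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep)  # rows = time, cols = channels
        data = frame.to_numpy().T
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channels=tuple(meta["channels"]),
        label=int(label),
        subject_id=str(subject_id or meta.get("subject_id", "S00")),
    )


def write_recording(rec: Recording, path: str | Path, fmt: str = "npy") -> Path:
    """Write a recording as matrix + JSON sidecar; returns the matrix path.

    ``fmt``: ``"npy"`` (lossless binary, channels x time) or ``"csv"``
    (time rows x channel columns, 17 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npy":
        matrix_path = path.with_suffix(".npy")
        np.save(matrix_path, rec.data)
    elif fmt == "csv":
        matrix_path = path.with_suffix(".csv")
        pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
            matrix_path, index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "fs": rec.fs,
        "channels": list(rec.channels),
        "label": rec.label,
        "subject_id": rec.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return matrix_path


def read_benchmark_recording(path: str | Path, dataset: str) -> Recording:
    """Adapter stub for restricted-access emotion EEG benchmarks.

    Not implemented: such corpora are distributed under access agreements
    and are neither shipped nor downloaded here. The shapes an adapter is
    expected to produce are either 62 channels x time at 200 Hz (film-clip
    benchmarks) or 32 channels x time at 128 Hz (consumer-headset
    recordings), with one label in {-1, 0, 1} per trial. Convert each
    trial to the matrix + sidecar format and use :func:`read_recording`.
    """
    raise NotImplementedError(
        f"no loader for restricted dataset {dataset!r}; convert trials to "
        "the matrix + sidecar format documented in this module"
    )


# ---------------------------------------------------------------------------
# Tensor persistence
# ---------------------------------------------------------------------------

def save_tensor(tensor: BandTensor, path: str | Path) -> None:
    """Persist a BandTensor as <path>.npz plus <path>.manifest.tsv."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"band_{b}": a for b, a in tensor.data.items()}
    np.savez(
        path.with_suffix(".npz"),
        labels=tensor.labels,
        groups=tensor.groups,
        subjects=tensor.subjects.astype(str),
        channels=np.array(tensor.channels, dtype=str),
        meta=np.array(
            json.dumps(
                {
                    "fs": tensor.fs,
                    "window_s": tensor.window_s,
                    "step_s": tensor.step_s,
                    "bands": list(tensor.data),
                }
            )
        ),
        **arrays,
    )
    tensor.manifest.to_csv(path.with_suffix(".manifest.tsv"), sep="\t", index=False)


def load_tensor(path: str | Path) -> BandTensor:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        data = {b: npz[f"band_{b}"] for b in meta["bands"]}
        labels = npz["labels"]
        groups = npz["groups"] if "groups" in npz else None
        subjects = npz["subjects"].astype(object)
        channels = tuple(str(c) for c in npz["channels"])
    manifest_path = path.with_suffix(".manifest.tsv")
    manifest = (
        pd.read_csv(manifest_path, sep="\t") if manifest_path.exists() else pd.DataFrame()
    )
    return BandTensor(
        data=data,
        labels=labels,
        subjects=subjects,
        channels=channels,
        fs=meta["fs"],
        window_s=meta["window_s"],
        step_s=meta["step_s"],
        manifest=manifest,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Metrics tables
# ---------------------------------------------------------------------------

def write_metrics(results, path: str | Path) -> pd.DataFrame:
    """Write CV/ablation results as a delimited ACC/STD table.

    Accepts an :class:`~eegfuse.training.AblationGrid`, a mapping of name
    -> CVResult, or a single CVResult. Cells are formatted to two decimals
    as ``"94.20/2.38"``. An empty input yields a header-only file.
    """
    from .training import AblationGrid, CVResult  # local import to avoid cycle

    if isinstance(results, AblationGrid):
        frame = results.to_frame()
    elif isinstance(results, CVResult):
        frame = pd.DataFrame({"acc_std": [str(results)]}, index=pd.Index(["cv"], name="run"))
    elif isinstance(results, dict):
        frame = pd.DataFrame(
            {"acc_std": [str(v) for v in results.values()]},
            index=pd.Index(list(results), name="run"),
        )
    else:
        raise TypeError(f"cannot format {type(results).__name__} as a metrics table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")
    return frame


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics`."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to re-execute a run: config, seed, inputs, outputs."""

    command: str
    seed: int | None
    config: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    package_version: str = ""
    python_version: str = field(default_factory=platform.python_version)
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        from . import __version__

        self.package_version = self.package_version or __version__
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))
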