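"""Training protocol, stratified k-fold cross-validation, and ablation.

Defaults follow the study protocol: Adam at learning rate 0.001 with
inverse-time decay 1e-5 per step, categorical cross-entropy, and 5-fold
cross-validation with an 8:2 train/test split per fold. Batch size 64,
at most 100 epochs with early stopping (patience 10) on validation loss,
restoring the best-epoch weights; these are desk-scale choices recorded
in every run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)

from . import nn
from .model import ECNAF
from .preprocessing import BandTensor, band_name

__all__ = [
    "TrainConfig",
    "History",
    "CVResult",
    "AblationGrid",
    "train",
    "cross_validate",
    "evaluate",
    "run_ablation",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    lr: float = 1e-3
    decay: float = 1e-5
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    min_epochs: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.decay < 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class History:
    """Per-epoch loss/accuracy curves from one training run."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def _batched_eval(
    model: ECNAF,
    xs: Mapping[str, np.ndarray],
    y: np.ndarray,
    batch_size: int = 256,
) -> tuple[float, float]:
    """Evaluation-mode mean loss and accuracy (%)."""
    n = y.shape[0]
    losses, correct = [], 0
    for lo in range(0, n, batch_size):
        batch = {b: xs[b][lo : lo + batch_size] for b in model.bands}
        yb = y[lo : lo + batch_size]
        probs = model.forward(batch, training=False)
        loss, _ = nn.cross_entropy(probs, yb)
        losses.append(loss * yb.shape[0])
        correct += int((np.argmax(probs, axis=1) == yb).sum())
    return float(np.sum(losses) / n), 100.0 * correct / n


def train(
    model: ECNAF,
    tensors: BandTensor,
    cfg: TrainConfig | None = None,
    val_tensors: BandTensor | None = None,
) -> History:
    """Train a model, early-stopping on validation loss.

    When ``val_tensors`` is not supplied, a stratified ``val_fraction``
    split is carved out of ``tensors``. Raises if the training labels
    contain a single class or if the loss turns non-finite.
    """
    cfg = cfg or TrainConfig()
    y = tensors.labels
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    if val_tensors is None and cfg.val_fraction > 0:
        # stratified split needs >= 1 sample per class on the validation side
        n_val = max(int(round(cfg.val_fraction * y.shape[0])), np.unique(y).size)
        if n_val < y.shape[0]:
            idx_tr, idx_val = train_test_split(
                np.arange(y.shape[0]),
                test_size=n_val,
                stratify=y,
                random_state=cfg.seed,
            )
            val_tensors = tensors.take(idx_val)
            tensors = tensors.take(idx_tr)
            y = tensors.labels
    xs = tensors.arrays(model.bands)
    n = y.shape[0]

    optimizer = nn.Adam(model.named_params(), lr=cfg.lr, decay=cfg.decay)
    rng = np.random.default_rng(cfg.seed)
    history = History()
    best_state, best_val, patience_left = None, np.inf, cfg.patience

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            batch = {b: xs[b][idx] for b in model.bands}
            yb = y[idx]
            probs = model.forward(batch, training=True)
            loss, grad = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {lo // cfg.batch_size}: "
                    f"loss={loss}; last batch size {yb.shape[0]}"
                )
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss * yb.shape[0]
            correct += int((np.argmax(probs, axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / n)
        history.train_acc.append(100.0 * correct / n)

        if val_tensors is not None:
            val_loss, val_acc = _batched_eval(
                model, val_tensors.arrays(model.bands), val_tensors.labels
            )
            history.val_loss.append(val_loss)
            history.val_acc.append(val_acc)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = model.get_state()
                history.best_epoch = epoch
                patience_left = cfg.patience
            else:
                patience_left -= 1
                # batch-norm running statistics need a floor of optimizer
                # steps before evaluation-mode loss is meaningful, so early
                # stopping only engages after min_epochs
                if patience_left <= 0 and epoch + 1 >= cfg.min_epochs:
                    break
    if best_state is not None:
        model.set_state(best_state)
    return history


def evaluate(model: ECNAF, tensors: BandTensor) -> tuple[float, np.ndarray]:
    """Accuracy (%) and a 3x3 confusion matrix on a labeled tensor."""
    if tensors.n_segments == 0:
        raise ValueError("empty evaluation set")
    preds = model.predict(tensors.arrays(model.bands))
    acc = 100.0 * float(np.mean(preds == tensors.labels))
    cm = confusion_matrix(tensors.labels, preds, labels=[0, 1, 2])
    return acc, cm


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold accuracies plus ACC/STD in %."""

    fold_acc: list[float]
    manifest: pd.DataFrame

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def std_acc(self) -> float:
        return float(np.std(self.fold_acc))

    def __str__(self) -> str:
        return f"{self.mean_acc:.2f}/{self.std_acc:.2f}"


def cross_validate(
    tensors: BandTensor,
    model_factory: Callable[[int], ECNAF],
    cfg: TrainConfig | None = None,
    k: int = 5,
    mode: str = "pooled",
) -> CVResult:
    """Stratified k-fold cross-validation at the segment level.

    ``pooled`` merges all subjects before folding; ``per_subject`` runs a
    separate k-fold per subject and reports each subject's mean fold
    accuracy as one entry; ``grouped`` keeps all windows of one source
    recording on the same side of every split (leakage-free: overlapping
    windows of a recording can otherwise reveal its identity, and with it
    the label). ``model_factory(seed)`` must return a fresh model. Folds
    are disjoint and their union covers every segment.
    """
    cfg = cfg or TrainConfig()
    if tensors.n_segments < k:
        raise ValueError("fewer segments than folds")
    if mode not in ("pooled", "per_subject", "grouped"):
        raise ValueError(f"unknown cross-validation mode {mode!r}")

    if mode == "per_subject":
        accs, frames = [], []
        for subject in pd.unique(tensors.subjects):
            sub = tensors.take(np.flatnonzero(tensors.subjects == subject))
            res = cross_validate(sub, model_factory, cfg, k=k, mode="pooled")
            accs.append(res.mean_acc)
            frame = res.manifest.copy()
            frame["subject_id"] = subject
            frames.append(frame)
        return CVResult(fold_acc=accs, manifest=pd.concat(frames, ignore_index=True))

    if mode == "grouped":
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = skf.split(np.zeros(tensors.n_segments), tensors.labels, tensors.groups)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = skf.split(np.zeros(tensors.n_segments), tensors.labels)
    fold_acc, rows = [], []
    for fold, (idx_tr, idx_te) in enumerate(splits):
        model = model_factory(cfg.seed + fold)
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        train(model, tensors.take(idx_tr), fold_cfg)
        acc, _ = evaluate(model, tensors.take(idx_te))
        fold_acc.append(acc)
        rows.append(
            {
                "fold": fold,
                "n_train": idx_tr.size,
                "n_test": idx_te.size,
                "test_indices": ",".join(map(str, idx_te)),
                "accuracy": acc,
            }
        )
    return CVResult(fold_acc=fold_acc, manifest=pd.DataFrame(rows))


@dataclass
class AblationGrid:
    """Grid of CV results over band subsets x fusion modes x combinations."""

    results: dict[tuple[str, str, str], CVResult]  # (bands, combo, mode) -> result

    def to_frame(self) -> pd.DataFrame:
        """ACC/STD table with rows = band subsets, columns = (combo, mode);
        the best cell per (row, combo) is flagged with ``*``."""
        rows = sorted({k[0] for k in self.results})
        combos = sorted({k[1] for k in self.results})
        modes = sorted({k[2] for k in self.results})
        table = {}
        for combo in combos:
            for mode in modes:
                col = []
                for bands in rows:
                    res = self.results.get((bands, combo, mode))
                    col.append("" if res is None else str(res))
                table[f"{combo}/{mode}"] = col
        frame = pd.DataFrame(table, index=pd.Index(rows, name="bands"))
        for combo in combos:
            cols = [f"{combo}/{m}" for m in modes]
            for bands in rows:
                vals = {
                    c: self.results[(bands, combo, c.split("/")[1])].mean_acc
                    for c in cols
                    if (bands, combo, c.split("/")[1]) in self.results
                }
                if vals:
                    best = max(vals, key=vals.get)
                    frame.loc[bands, best] += "*"
        return frame

    def __len__(self) -> int:
        return len(self.results)


def run_ablation(
    tensors: BandTensor,
    band_subsets: Sequence[Sequence[str]],
    fusion_modes: Sequence[str],
    combos: Sequence[str] = ("All",),
    cfg: TrainConfig | None = None,
    k: int = 5,
    mode: str = "pooled",
) -> AblationGrid:
    """Cross-validate every (band subset, fusion mode, channel combination).

    Single-band subsets are run with fusion bypassed regardless of the
    requested fusion mode (they appear once per mode column for layout
    compatibility).
    """
    cfg = cfg or TrainConfig()
    results: dict[tuple[str, str, str], CVResult] = {}
    for combo in combos:
        selected = tensors.select_channels(combo)
        n_ch = len(selected.channels)
        for bands in band_subsets:
            names = tuple(band_name(b) for b in bands)
            sub = selected.select_bands(names)
            for fusion in fusion_modes:
                eff_fusion = "none" if len(names) == 1 else fusion
                factory = lambda seed, nb=names, fm=eff_fusion, nc=n_ch: ECNAF(
                    nb, nc, fusion=fm, seed=seed
                )
                res = cross_validate(sub, factory, cfg, k=k, mode=mode)
                results[("+".join(names), combo, fusion)] = res
    return AblationGrid(results=results)
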