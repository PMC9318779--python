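"""Per-band convolutional backbone, band-fusion units, and classifier.

The network has three stages:

1. **Backbone** (one independent branch per selected band): two strided
   convolutions (32 then 64 filters, kernel 5, ReLU), average pooling,
   batch normalization, and channel-wise dropout. A 2000-sample window
   maps to a (249, 64) feature map.
2. **Fusion** of the per-band feature maps: element-wise ``add``,
   element-wise ``mult``, or the sigmoid band-attention unit. The
   attention unit time-pools each band's feature map to a 64-vector
   ``v_k``, forms a scalar gate ``sigmoid(q_k . v_k)`` from a learnable
   per-band query ``q_k`` (initialized to zero, so training starts from
   neutral 0.5 gates), and sums the gated feature maps.
3. **Classifier**: two 128-filter convolutions, pooling, batch norm,
   dropout, two 256-filter convolutions, global average pooling, dropout,
   and a 3-way softmax. A (249, 64) input maps through
   245 -> 245 -> 122 -> 118 -> 118 -> 256 -> 3.

Convolution kernels are 5 throughout and the second convolution of each
pair is 'same'-padded; classifier convolutions use stride 1. These choices
reproduce every stage shape above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .preprocessing import band_name

__all__ = [
    "BackboneConfig",
    "ClassifierConfig",
    "FusionSpec",
    "FUSION_MODES",
    "fuse_add",
    "fuse_mult",
    "AttentionFusion",
    "ECNAF",
    "build_ecnaf",
    "backbone_stage_lengths",
    "classifier_stage_lengths",
]

FUSION_MODES = ("add", "mult", "attention", "attention_prod", "none")


@dataclass(frozen=True)
class BackboneConfig:
    """Per-band feature extractor settings."""

    filters1: int = 32
    filters2: int = 64
    kernel: int = 5
    pool: int = 2
    dropout: float = 0.2

    @property
    def n_features(self) -> int:
        return self.filters2


@dataclass(frozen=True)
class ClassifierConfig:
    """Classification head settings."""

    filters_a: int = 128
    filters_b: int = 256
    kernel: int = 5
    pool: int = 2
    dropout: float = 0.5
    n_classes: int = 3


@dataclass(frozen=True)
class FusionSpec:
    """Which bands are fused and how."""

    bands: tuple[str, ...]
    mode: str = "attention"

    def __post_init__(self) -> None:
        names = tuple(band_name(b) for b in self.bands)
        object.__setattr__(self, "bands", names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate bands in fusion spec")
        if self.mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if len(names) < 1:
            raise ValueError("at least one band required")
        if len(names) == 1 and self.mode != "none":
            raise ValueError(
                "a single band bypasses fusion; use mode='none' for one band"
            )
        if len(names) > 1 and self.mode == "none":
            raise ValueError("mode 'none' is only valid for a single band")


def backbone_stage_lengths(n: int, cfg: BackboneConfig | None = None) -> list[int]:
    """Temporal lengths after each backbone stage (conv1, conv2, pool)."""
    cfg = cfg or BackboneConfig()
    l1 = nn.conv_out_len(n, cfg.kernel, 2, "same")
    l2 = nn.conv_out_len(l1, cfg.kernel, 2, "valid")
    return [l1, l2, l2 // cfg.pool]


def classifier_stage_lengths(n: int, cfg: ClassifierConfig | None = None) -> list[int]:
    """Temporal lengths after conv1, conv2, pool, conv3, conv4."""
    cfg = cfg or ClassifierConfig()
    l1 = nn.conv_out_len(n, cfg.kernel, 1, "valid")
    l2 = nn.conv_out_len(l1, cfg.kernel, 1, "same")
    lp = l2 // cfg.pool
    l3 = nn.conv_out_len(lp, cfg.kernel, 1, "valid")
    l4 = nn.conv_out_len(l3, cfg.kernel, 1, "same")
    return [l1, l2, lp, l3, l4]


def _build_backbone(
    c_in: int, cfg: BackboneConfig, rng: np.random.Generator, dtype
) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv1D(c_in, cfg.filters1, cfg.kernel, stride=2, padding="same", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Conv1D(cfg.filters1, cfg.filters2, cfg.kernel, stride=2, padding="valid", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.AvgPool1D(cfg.pool),
            nn.BatchNorm1D(cfg.filters2, dtype=dtype),
            nn.SpatialDropout1D(cfg.dropout, rng=rng),
        ]
    )


def _build_classifier(
    c_in: int, cfg: ClassifierConfig, rng: np.random.Generator, dtype
) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv1D(c_in, cfg.filters_a, cfg.kernel, stride=1, padding="valid", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Conv1D(cfg.filters_a, cfg.filters_a, cfg.kernel, stride=1, padding="same", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.AvgPool1D(cfg.pool),
            nn.BatchNorm1D(cfg.filters_a, dtype=dtype),
            nn.Dropout(cfg.dropout, rng=rng),
            nn.Conv1D(cfg.filters_a, cfg.filters_b, cfg.kernel, stride=1, padding="valid", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Conv1D(cfg.filters_b, cfg.filters_b, cfg.kernel, stride=1, padding="same", rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.GlobalAvgPool1D(),
            nn.Dropout(cfg.dropout, rng=rng),
            nn.Dense(cfg.filters_b, cfg.n_classes, rng=rng, dtype=dtype),
        ]
    )


# ---------------------------------------------------------------------------
# Fusion operators
# ---------------------------------------------------------------------------

def _check_shapes(features: Sequence[np.ndarray], min_count: int = 2) -> None:
    if len(features) < min_count:
        raise ValueError(f"fusion requires at least {min_count} band features")
    shape = features[0].shape
    for f in features[1:]:
        if f.shape != shape:
            raise ValueError(f"feature shape mismatch: {f.shape} vs {shape}")


def fuse_add(features: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise sum of per-band feature maps (order-independent)."""
    _check_shapes(features)
    out = features[0].copy()
    for f in features[1:]:
        out += f
    return out


def fuse_mult(features: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise product of per-band feature maps (order-independent)."""
    _check_shapes(features)
    out = features[0].copy()
    for f in features[1:]:
        out *= f
    return out


class AttentionFusion(nn.Layer):
    """Sigmoid band-attention unit.

    Each band feature map ``F_k`` (batch, time, 64) is time-averaged to a
    vector ``v_k``; a learnable query ``q_k`` produces the scalar gate
    ``Weight_k = sigmoid(q_k . v_k)`` in (0, 1); the fused map is
    ``sum_k Weight_k * F_k``. Queries start at zero so every gate starts
    at the neutral value 0.5.
    """

    def __init__(self, bands: Sequence[str], n_features: int, dtype=np.float32) -> None:
        super().__init__()
        self.bands = tuple(bands)
        self.n_features = n_features
        for b in self.bands:
            self.params[f"q_{b}"] = np.zeros(n_features, dtype=dtype)

    def forward_bands(
        self, features: Mapping[str, np.ndarray], training: bool = False
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        feats = [features[b] for b in self.bands]
        _check_shapes(feats, min_count=1)
        if feats[0].shape[2] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature maps, got {feats[0].shape[2]}"
            )
        self._cache = {}
        gates: dict[str, np.ndarray] = {}
        fused = np.zeros_like(feats[0])
        for b, f in zip(self.bands, feats):
            v = f.mean(axis=1)  # (batch, n_features)
            logits = v @ self.params[f"q_{b}"]
            w = 1.0 / (1.0 + np.exp(-logits))  # (batch,)
            fused += w[:, None, None] * f
            self._cache[b] = (f, v, w)
            gates[b] = w
        self._gates = gates
        return fused, gates

    def backward(self, grad: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for b in self.bands:
            f, v, w = self._cache[b]
            q = self.params[f"q_{b}"]
            dw = (grad * f).sum(axis=(1, 2))  # (batch,)
            dlogit = dw * w * (1.0 - w)
            self.grads[f"q_{b}"] = dlogit @ v
            df = w[:, None, None] * grad
            df += (dlogit[:, None] * q[None, :])[:, None, :] / f.shape[1]
            out[b] = df
        return out


class _ProductAttentionFusion(nn.Layer):
    """Literal product-gating variant of the attention unit.

    The element-wise product ``P`` of all selected band features is pooled
    to a vector, gated by ``sigmoid(q . v)`` with a single query, and the
    fused output is ``Weight * P``. Kept for comparison with the weighted
    per-band sum used by :class:`AttentionFusion`.
    """

    def __init__(self, bands: Sequence[str], n_features: int, dtype=np.float32) -> None:
        super().__init__()
        self.bands = tuple(bands)
        self.n_features = n_features
        self.params["q"] = np.zeros(n_features, dtype=dtype)

    def forward_bands(self, features, training=False):
        feats = [features[b] for b in self.bands]
        _check_shapes(feats)
        prod = fuse_mult(feats)
        v = prod.mean(axis=1)
        w = 1.0 / (1.0 + np.exp(-(v @ self.params["q"])))
        self._cache = (feats, prod, v, w)
        gates = {b: w for b in self.bands}
        self._gates = gates
        return w[:, None, None] * prod, gates

    def backward(self, grad):
        feats, prod, v, w = self._cache
        q = self.params["q"]
        dw = (grad * prod).sum(axis=(1, 2))
        dlogit = dw * w * (1.0 - w)
        self.grads["q"] = dlogit @ v
        dprod = w[:, None, None] * grad
        dprod += (dlogit[:, None] * q[None, :])[:, None, :] / prod.shape[1]
        out = {}
        for i, b in enumerate(self.bands):
            others = np.ones_like(prod)
            for j, f in enumerate(feats):
                if j != i:
                    others *= f
            out[b] = dprod * others
        return out


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------

class ECNAF:
    """Band-attention EEG emotion classifier.

    One independent convolutional backbone per selected band (no weight
    sharing), a fusion unit, and a shared classification head producing
    3-class probabilities.

    Parameters
    ----------
    bands
        Ordered band subset, e.g. ``("delta", "beta", "gamma")``.
    n_channels
        Number of input electrodes per window.
    fusion
        ``"add"``, ``"mult"``, ``"attention"``, ``"attention_prod"`` or
        ``"none"`` (single band only).
    seed
        Seeds parameter initialization and dropout; identical seeds give
        identical initial parameters.
    """

    def __init__(
        self,
        bands: Sequence[str],
        n_channels: int,
        fusion: str = "attention",
        seed: int = 0,
        backbone_cfg: BackboneConfig | None = None,
        classifier_cfg: ClassifierConfig | None = None,
        dtype=np.float32,
    ) -> None:
        spec = FusionSpec(tuple(bands), fusion)
        self.spec = spec
        self.n_channels = int(n_channels)
        self.seed = int(seed)
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.classifier_cfg = classifier_cfg or ClassifierConfig()
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.backbones = {
            b: _build_backbone(self.n_channels, self.backbone_cfg, rng, dtype)
            for b in spec.bands
        }
        nf = self.backbone_cfg.n_features
        if spec.mode == "attention":
            self.fusion: nn.Layer | None = AttentionFusion(spec.bands, nf, dtype=dtype)
        elif spec.mode == "attention_prod":
            self.fusion = _ProductAttentionFusion(spec.bands, nf, dtype=dtype)
        else:
            self.fusion = None
        self.classifier = _build_classifier(nf, self.classifier_cfg, rng, dtype)

    # -- forward / backward -------------------------------------------------

    @property
    def bands(self) -> tuple[str, ...]:
        return self.spec.bands

    def _band_inputs(self, xs: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for b in self.bands:
            if b not in xs:
                raise KeyError(f"missing band {b!r} in model input")
            x = np.asarray(xs[b], dtype=self.dtype)
            if x.ndim != 3 or x.shape[2] != self.n_channels:
                raise ValueError(
                    f"band {b}: expected (batch, time, {self.n_channels}) input, "
                    f"got shape {x.shape}"
                )
            out[b] = x
        return out

    def forward(
        self, xs: Mapping[str, np.ndarray], training: bool = False
    ) -> np.ndarray:
        """Class probabilities of shape (batch, 3)."""
        xs = self._band_inputs(xs)
        feats = {
            b: self.backbones[b].forward(xs[b], training=training) for b in self.bands
        }
        self._last_feats = feats
        if self.fusion is not None:
            fused, self._last_gates = self.fusion.forward_bands(feats, training=training)
        elif self.spec.mode == "add":
            fused = fuse_add([feats[b] for b in self.bands])
            self._last_gates = None
        elif self.spec.mode == "mult":
            fused = fuse_mult([feats[b] for b in self.bands])
            self._last_gates = None
        else:  # single band
            fused = feats[self.bands[0]]
            self._last_gates = None
        logits = self.classifier.forward(fused, training=training)
        return nn.softmax(logits)

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.classifier.backward(grad_logits)
        if self.fusion is not None:
            band_grads = self.fusion.backward(grad)
        elif self.spec.mode == "add":
            band_grads = {b: grad for b in self.bands}
        elif self.spec.mode == "mult":
            feats = self._last_feats
            band_grads = {}
            for b in self.bands:
                others = np.ones_like(grad)
                for c in self.bands:
                    if c != b:
                        others *= feats[c]
                band_grads[b] = grad * others
        else:
            band_grads = {self.bands[0]: grad}
        for b in self.bands:
            self.backbones[b].backward(band_grads[b])

    def predict(self, xs: Mapping[str, np.ndarray], batch_size: int = 256) -> np.ndarray:
        """Predicted class indices; argmax ties break toward the lowest class."""
        n = next(iter(xs.values())).shape[0]
        preds = np.empty(n, dtype=np.int64)
        for lo in range(0, n, batch_size):
            batch = {b: xs[b][lo : lo + batch_size] for b in self.bands}
            preds[lo : lo + batch_size] = np.argmax(self.forward(batch), axis=1)
        return preds

    def attention_gates(self, xs: Mapping[str, np.ndarray]) -> dict[str, float]:
        """Mean sigmoid gate per band over the given inputs (attention mode)."""
        if self.fusion is None:
            raise ValueError("model has no attention fusion unit")
        self.forward(xs, training=False)
        return {b: float(np.mean(w)) for b, w in self._last_gates.items()}

    # -- parameters ---------------------------------------------------------

    def named_params(self) -> dict[str, tuple[nn.Layer, str]]:
        out: dict[str, tuple[nn.Layer, str]] = {}
        for b in self.bands:
            out.update(self.backbones[b].named_params(f"backbone.{b}."))
        if self.fusion is not None:
            for name in self.fusion.params:
                out[f"fusion.{name}"] = (self.fusion, name)
        out.update(self.classifier.named_params("classifier."))
        return out

    def parameter_count(self) -> int:
        return int(sum(layer.params[n].size for layer, n in self.named_params().values()))

    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: layer.params[n].copy() for k, (layer, n) in self.named_params().items()}
        for b in self.bands:
            bn = self._batchnorms(self.backbones[b])
            for i, layer in enumerate(bn):
                state[f"backbone.{b}.bn{i}.running_mean"] = layer.running_mean.copy()
                state[f"backbone.{b}.bn{i}.running_var"] = layer.running_var.copy()
        for i, layer in enumerate(self._batchnorms(self.classifier)):
            state[f"classifier.bn{i}.running_mean"] = layer.running_mean.copy()
            state[f"classifier.bn{i}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for k, (layer, n) in self.named_params().items():
            layer.params[n] = np.array(state[k], dtype=layer.params[n].dtype)
        for b in self.bands:
            for i, layer in enumerate(self._batchnorms(self.backbones[b])):
                layer.running_mean = np.array(state[f"backbone.{b}.bn{i}.running_mean"])
                layer.running_var = np.array(state[f"backbone.{b}.bn{i}.running_var"])
        for i, layer in enumerate(self._batchnorms(self.classifier)):
            layer.running_mean = np.array(state[f"classifier.bn{i}.running_mean"])
            layer.running_var = np.array(state[f"classifier.bn{i}.running_var"])

    @staticmethod
    def _batchnorms(stack: nn.Sequential) -> list[nn.BatchNorm1D]:
        return [l for l in stack.layers if isinstance(l, nn.BatchNorm1D)]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a reloadable checkpoint (config JSON + parameter arrays)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        config = {
            "bands": list(self.bands),
            "fusion": self.spec.mode,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "backbone_cfg": asdict(self.backbone_cfg),
            "classifier_cfg": asdict(self.classifier_cfg),
            "dtype": self.dtype.name,
        }
        (path / "config.json").write_text(json.dumps(config, indent=2))
        np.savez(path / "params.npz", **self.get_state())

    @classmethod
    def load(cls, path: str | Path) -> "ECNAF":
        path = Path(path)
        config = json.loads((path / "config.json").read_text())
        model = cls(
            bands=config["bands"],
            n_channels=config["n_channels"],
            fusion=config["fusion"],
            seed=config["seed"],
            backbone_cfg=BackboneConfig(**config["backbone_cfg"]),
            classifier_cfg=ClassifierConfig(**config["classifier_cfg"]),
            dtype=np.dtype(config["dtype"]),
        )
        with np.load(path / "params.npz") as state:
            model.set_state(dict(state))
        return model


def build_ecnaf(
    bands: Sequence[str],
    n_channels: int,
    fusion_mode: str = "attention",
    seed: int = 0,
    **kwargs,
) -> ECNAF:
    """Assemble the end-to-end model (one backbone branch per band)."""
    return ECNAF(bands, n_channels, fusion=fusion_mode, seed=seed, **kwargs)
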