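"""Dual-backbone feature-fusion classifier with frozen and fine-tune modes.

The architecture mirrors the transfer-learning design the pipeline is
built around: two convolutional backbones process the same input, each is
reduced to a feature vector by global average pooling, the two vectors are
concatenated, and a fully connected head with dropout ends in a softmax
over the three classes (healthy / nodule / polyp). Two training regimes
are supported:

``frozen``
    All backbone layers are non-trainable; only the head learns.
``fine_tune_last_k``
    Exactly the last ``k`` entries of each backbone's flat layer list
    (default ``k = 20``) are unfrozen in addition to the head. "Layer"
    here means one entry of the backbone's own layer ordering —
    convolution, normalization, activation and pooling entries all count,
    and the chosen count is recorded on the built model so the convention
    is auditable.

Training uses Adam (learning rate 0.001), batch size 32, at most 30
epochs and early stopping on validation loss with best-weight restore —
the fixed hyperparameter set under which model variants are compared.

The built-in ``tiny`` backbone (a few conv/batch-norm blocks, ~10^5
parameters in the fused model) trains in seconds on a CPU and needs no
downloaded weights; other backbones can be plugged in through
:func:`register_backbone`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "BackboneSpec",
    "FusionConfig",
    "TrainConfig",
    "FusionModel",
    "register_backbone",
    "build_fusion_model",
    "prepare_inputs",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Identifies a convolutional feature extractor.

    ``layer_count`` is populated after the backbone is built. Only the
    ``tiny`` backbone ships with the package (it builds with no downloads);
    further architectures can be added via :func:`register_backbone`.
    """

    name: str = "tiny"
    pretrained: bool = False
    input_size: tuple[int, int, int] = (32, 32, 1)  # (h, w, channels)
    layer_count: int | None = None


@dataclass(frozen=True)
class FusionConfig:
    """Architecture of the fused classifier."""

    backbones: tuple[BackboneSpec, BackboneSpec] = (BackboneSpec(), BackboneSpec())
    fc_sizes: tuple[int, ...] = (256,)
    dropout_rate: float = 0.3
    n_classes: int = 3
    mode: str = "frozen"  # "frozen" | "fine_tune_last_k"
    k: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("frozen", "fine_tune_last_k"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.mode == "fine_tune_last_k" and self.k < 1:
            raise ValueError("k must be >= 1 in fine_tune_last_k mode")
        a, b = self.backbones
        if a.input_size != b.input_size:
            raise ValueError("both backbones must share one input size")


@dataclass(frozen=True)
class TrainConfig:
    """Fixed training hyperparameters for controlled comparisons."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training hyperparameters")


# --------------------------------------------------------------------------
# backbone registry

_BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, builder: Callable) -> None:
    """Register ``builder(spec, rng) -> (layers, feature_width)``."""
    _BACKBONES[name] = builder


def _build_tiny(spec: BackboneSpec, rng: np.random.Generator):
    """Small 5-block conv net: 22 layer entries, ~53k parameters.

    Spatial extent is divided by 32 (five 2x2 pools), so the input sides
    must be multiples of 32. Feature width after global pooling is 64.
    """
    h, w, c = spec.input_size
    if h % 32 or w % 32:
        raise ValueError(f"tiny backbone needs input sides divisible by 32, got {h}x{w}")
    widths = [16, 24, 32, 48, 64]
    layers: list[nn.Layer] = [nn.Conv2D(c, 8, 3, rng), nn.ReLU()]
    c_in = 8
    for c_out in widths:
        layers += [
            nn.Conv2D(c_in, c_out, 3, rng),
            nn.BatchNorm2D(c_out),
            nn.ReLU(),
            nn.MaxPool2D(2),
        ]
        c_in = c_out
    return layers, widths[-1]


register_backbone("tiny", _build_tiny)


# --------------------------------------------------------------------------
# model

class FusionModel:
    """Two pooled backbone branches, concatenated, with a dense head."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.seed = seed

        specs = []
        self.branches: list[list[nn.Layer]] = []
        self.feature_widths: list[int] = []
        for spec in config.backbones:
            if spec.name not in _BACKBONES:
                raise ValueError(
                    f"no builder registered for backbone {spec.name!r}; "
                    f"available: {sorted(_BACKBONES)}"
                )
            layers, width = _BACKBONES[spec.name](spec, rng)
            self.branches.append(layers)
            self.feature_widths.append(width)
            specs.append(replace(spec, layer_count=len(layers)))
        self.backbone_specs = tuple(specs)
        self.pools = [nn.GlobalAvgPool(), nn.GlobalAvgPool()]

        for layers in self.branches:
            if config.mode == "frozen":
                for layer in layers:
                    layer.trainable = False
            else:
                if config.k > len(layers):
                    raise ValueError(
                        f"k={config.k} exceeds backbone depth {len(layers)}"
                    )
                for layer in layers[: len(layers) - config.k]:
                    layer.trainable = False
                for layer in layers[len(layers) - config.k :]:
                    layer.trainable = True

        #: fused feature width = sum of branch widths (concatenation)
        self.fused_width = sum(self.feature_widths)
        head: list[nn.Layer] = []
        d_in = self.fused_width
        for d_out in config.fc_sizes:
            head += [nn.Dense(d_in, d_out, rng)]
            head += [nn.ReLU()]
            d_in = d_out
        head += [nn.Dropout(config.dropout_rate, rng)]
        head += [nn.Dense(d_in, config.n_classes, rng)]
        self.head = head
        self._rng = rng

    # -- introspection -----------------------------------------------------

    def trainable_layer_counts(self) -> tuple[int, int]:
        """Number of trainable layer entries per backbone (layer walk)."""
        return tuple(sum(l.trainable for l in layers) for layers in self.branches)

    def trainable_backbone_params(self) -> int:
        return sum(
            l.n_params for layers in self.branches for l in layers if l.trainable
        )

    def n_trainable_params(self) -> int:
        head = sum(l.n_params for l in self.head if l.trainable)
        return self.trainable_backbone_params() + head

    def backbone_state(self) -> dict[str, np.ndarray]:
        out = {}
        for bi, layers in enumerate(self.branches):
            out.update(nn.layers_state(layers, prefix=f"branch{bi}."))
        return out

    # -- compute -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities (rows sum to 1) for a prepared input batch."""
        feats = []
        for layers, pool in zip(self.branches, self.pools):
            f = nn.run_forward(layers, x, train)
            feats.append(pool.forward(f, train))
        fused = np.concatenate(feats, axis=1)
        self._fused = fused
        logits = nn.run_forward(self.head, fused, train)
        return nn.softmax(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = nn.run_backward(self.head, dlogits)
        start = 0
        for layers, pool, width in zip(self.branches, self.pools, self.feature_widths):
            if any(l.trainable for l in layers):
                grad = pool.backward(dfused[:, start : start + width])
                nn.run_backward(layers, grad)
            start += width

    def all_layers(self) -> list[nn.Layer]:
        return [l for layers in self.branches for l in layers] + self.pools + self.head

    def state(self) -> dict[str, np.ndarray]:
        out = self.backbone_state()
        out.update(nn.layers_state(self.head, prefix="head."))
        return out

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        for k, v in state.items():
            own[k][...] = v

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = prepare_inputs(x)
        out = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)


def build_fusion_model(config: FusionConfig, seed: int = 0) -> FusionModel:
    """Build the fusion classifier; weights are seeded deterministically."""
    return FusionModel(config, seed=seed)


def prepare_inputs(x) -> np.ndarray:
    """Coerce images to the (N, C, H, W) float tensor the model consumes.

    Accepts a list of ImageFrames or an array shaped (N, H, W) or
    (N, H, W, C), with 0–255 intensities; output is scaled to [-1, 1].
    """
    if isinstance(x, np.ndarray) and x.ndim == 4 and x.shape[1] in (1, 3):
        return x  # already prepared
    if not isinstance(x, np.ndarray):
        x = np.stack([np.asarray(getattr(f, "pixels", f), dtype=float) for f in x])
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    elif x.ndim == 4:
        x = x.transpose(0, 3, 1, 2)
    else:
        raise ValueError(f"cannot interpret input of shape {x.shape}")
    return x / 127.5 - 1.0


def train(
    model: FusionModel,
    train_set: tuple,
    val_set: tuple,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train the fused model; returns the per-epoch history.

    ``train_set`` and ``val_set`` are ``(images, labels)`` pairs. Stops
    early when validation loss has not improved for ``patience`` epochs and
    restores the best-scoring weights. Deterministic given the config seed
    (same seed, same data, same backend => identical history).
    """
    if config is None:
        config = TrainConfig()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    x_tr, x_va = prepare_inputs(x_tr), prepare_inputs(x_va)
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = model.config.n_classes
    for y in (y_tr, y_va):
        if y.min() < 0 or y.max() >= n_classes:
            raise ValueError(f"labels outside [0, {n_classes - 1}]")

    rng = np.random.default_rng(config.seed)
    for layer in model.all_layers():
        if isinstance(layer, nn.Dropout):
            layer.rng = rng
    opt = nn.Adam(model.all_layers(), lr=config.learning_rate)

    best_loss = np.inf
    best_state: dict | None = None
    since_best = 0
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        losses, accs = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs = model.forward(xb, train=True)
            losses.append(nn.cross_entropy(probs, yb))
            accs.append(float((probs.argmax(axis=1) == yb).mean()))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward((probs - onehot) / len(yb))
            opt.step()

        val_probs = model.predict_proba(x_va)
        val_loss = nn.cross_entropy(val_probs, y_va)
        val_acc = float((val_probs.argmax(axis=1) == y_va).mean())
        rows.append(
            dict(
                epoch=epoch,
                train_loss=float(np.mean(losses)),
                train_acc=float(np.mean(accs)),
                val_loss=val_loss,
                val_acc=val_acc,
            )
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = {k: v.copy() for k, v in model.state().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_state is not None:
        model.set_state(best_state)
    return pd.DataFrame(rows)


def predict(model: FusionModel, frames) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class probabilities for a batch of frames.

    Labels are the argmax of the probability rows; exact ties resolve to
    the lowest class index.
    """
    probs = model.predict_proba(frames)
    return probs.argmax(axis=1), probs


def save_checkpoint(model: FusionModel, path) -> None:
    """Serialize weights + architecture config to an .npz checkpoint."""
    cfg = model.config
    meta = dict(
        backbones=[
            dict(name=s.name, pretrained=s.pretrained, input_size=list(s.input_size))
            for s in cfg.backbones
        ],
        fc_sizes=list(cfg.fc_sizes),
        dropout_rate=cfg.dropout_rate,
        n_classes=cfg.n_classes,
        mode=cfg.mode,
        k=cfg.k,
        seed=model.seed,
    )
    np.savez(path, __config__=np.array(json.dumps(meta)), **model.state())


def load_checkpoint(path) -> FusionModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = FusionConfig(
        backbones=tuple(
            BackboneSpec(
                name=b["name"],
                pretrained=b["pretrained"],
                input_size=tuple(b["input_size"]),
            )
            for b in meta["backbones"]
        ),
        fc_sizes=tuple(meta["fc_sizes"]),
        dropout_rate=meta["dropout_rate"],
        n_classes=meta["n_classes"],
        mode=meta["mode"],
        k=meta["k"],
    )
    model = FusionModel(cfg, seed=meta["seed"])
    model.set_state(state)
    return model
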