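"""Multiview CNN sleep-posture classifier.

One shared convolutional backbone embeds every radar's echo map, an
element-wise pooling across the view axis fuses the per-radar embeddings
into a single feature vector, and a fully connected head classifies it.
Because the pooling is permutation-invariant and the backbone weights are
shared, the classifier accepts any number of views — which is what makes
retraining under different radar subsets (the ablation protocol) cheap.

Training follows the standard recipe for this task: cross-entropy loss
with the AdamW optimiser, learning rate 0.001, betas (0.9, 0.999).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .labels import COARSE_LABELS, FINE_LABELS, coarse_map  # noqa: F401  (re-exported)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "MVCNNClassifier",
    "build_model",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "BACKBONES",
    "STUB_BACKBONES",
]

#: Backbones buildable in this package (pure NumPy, CPU-sized).
BACKBONES = ("tiny_cnn", "resnet_mini", "densenet_mini")

#: Names registered for interface compatibility but not provided here:
#: full-scale torch-style extractors and the attention/hypercomplex models.
STUB_BACKBONES = ("resnet50", "densenet121", "efficientnet_b0", "phresnet50", "attention56", "swin_t")


@dataclass
class ModelSpec:
    """Architecture description for the multiview classifier."""

    backbone: str = "tiny_cnn"
    n_views: int = 8
    n_classes: int = 4
    pooling: str = "max"  # or "mean"
    input_size: int = 32
    head: tuple = (64,)

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.n_classes not in (4, 9):
            raise ValueError("n_classes must be 4 (coarse) or 9 (fine)")
        if self.pooling not in ("max", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.backbone in STUB_BACKBONES:
            raise ValueError(
                f"backbone {self.backbone!r} is a registry stub without an implementation "
                f"in this package; use one of {BACKBONES}"
            )
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; expected one of {BACKBONES}")

    @property
    def labels(self) -> tuple:
        return COARSE_LABELS if self.n_classes == 4 else FINE_LABELS


@dataclass
class TrainConfig:
    """Optimisation recipe; defaults follow the task's standard settings."""

    learning_rate: float = 1e-3
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.01
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        b1, b2 = self.betas
        if not (0 < b1 < b2 < 1):
            raise ValueError("betas must satisfy 0 < beta1 < beta2 < 1")


def _make_backbone(name: str, rng) -> tuple:
    """Returns (backbone Sequential mapping (n,1,s,s)->(n,F), feature dim)."""
    if name == "tiny_cnn":
        seq = nn.Sequential(
            nn.Conv2d(1, 16, rng=rng), nn.ReLU(), nn.MaxPool2d(),
            nn.Conv2d(16, 32, rng=rng), nn.ReLU(), nn.MaxPool2d(),
            nn.Conv2d(32, 64, rng=rng), nn.ReLU(), nn.MaxPool2d(),
            nn.GlobalAvgPool(),
        )
        return seq, 64
    if name == "resnet_mini":
        seq = nn.Sequential(
            nn.Conv2d(1, 16, rng=rng), nn.ReLU(), nn.MaxPool2d(),
            nn.ResidualBlock(16, rng=rng), nn.MaxPool2d(),
            nn.Conv2d(16, 32, rng=rng), nn.ReLU(),
            nn.ResidualBlock(32, rng=rng), nn.MaxPool2d(),
            nn.GlobalAvgPool(),
        )
        return seq, 32
    if name == "densenet_mini":
        seq = nn.Sequential(
            nn.Conv2d(1, 16, rng=rng), nn.ReLU(), nn.MaxPool2d(),
            nn.DenseBlock(16, 16, rng=rng), nn.MaxPool2d(),
            nn.DenseBlock(32, 16, rng=rng), nn.MaxPool2d(),
            nn.GlobalAvgPool(),
        )
        return seq, 48
    raise ValueError(f"unknown backbone {name!r}")  # pragma: no cover - guarded by ModelSpec


class MVCNNClassifier:
    """Shared-backbone multiview network: views -> pooled features -> logits."""

    def __init__(self, spec: ModelSpec, rng=None):
        rng = np.random.default_rng(rng)
        self.spec = spec
        self.backbone, self.feature_dim = _make_backbone(spec.backbone, rng)
        head_layers = []
        d = self.feature_dim
        for width in spec.head:
            head_layers += [nn.Dense(d, width, rng=rng), nn.ReLU()]
            d = width
        head_layers.append(nn.Dense(d, spec.n_classes, rng=rng))
        self.head = nn.Sequential(*head_layers)
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, n_views, H, W) single-channel maps -> (batch, n_classes) logits."""
        if x.ndim != 4:
            raise ValueError("expected input of shape (batch, n_views, H, W)")
        b, v, h, w = x.shape
        feats = self.backbone.forward(x.reshape(b * v, 1, h, w)).reshape(b, v, self.feature_dim)
        if self.spec.pooling == "max":
            self._pool_argmax = feats.argmax(axis=1)  # (b, F)
            pooled = feats.max(axis=1)
        else:
            pooled = feats.mean(axis=1)
        self._cache = (b, v, h, w)
        return self.head.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> None:
        b, v, h, w = self._cache
        dpooled = self.head.backward(dlogits)  # (b, F)
        dfeats = np.zeros((b, v, self.feature_dim))
        if self.spec.pooling == "max":
            np.put_along_axis(dfeats, self._pool_argmax[:, None, :], dpooled[:, None, :], axis=1)
        else:
            dfeats += dpooled[:, None, :] / v
        self.backbone.backward(dfeats.reshape(b * v, self.feature_dim))

    def param_items(self):
        yield from self.backbone.param_items()
        yield from self.head.param_items()

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.param_items())

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(nn.softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def build_model(spec: ModelSpec, seed: int = 0) -> MVCNNClassifier:
    return MVCNNClassifier(spec, rng=np.random.default_rng(seed))


def train(model: MVCNNClassifier, x: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None, x_val=None, y_val=None,
          verbose: bool = False) -> dict:
    """Fit the classifier; returns a per-epoch history.

    x : (n, n_views, H, W); y : int class indices.  Deterministic given
    ``config.seed`` (shuffling is the only stochastic element; weights
    are initialised in build_model).
    """
    config = config or TrainConfig()
    if len(x) == 0:
        raise ValueError("empty training set")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain >= 2 classes")
    if len(classes) < model.spec.n_classes:
        import warnings

        warnings.warn(
            f"only {len(classes)} of {model.spec.n_classes} classes present in training data",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    opt = nn.AdamW(model.param_items(), lr=config.learning_rate, betas=config.betas,
                   weight_decay=config.weight_decay)
    history = {"epoch": [], "loss": [], "accuracy": [], "val_accuracy": []}
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x[idx])
            loss, dlogits = nn.cross_entropy_with_logits(logits, y[idx])
            if config.learning_rate > 0:
                model.backward(dlogits)
                opt.step()
            losses.append(loss * len(idx))
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["epoch"].append(epoch)
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(n_correct / n)
        if x_val is not None:
            val_acc, _ = evaluate(model, x_val, y_val)
            history["val_accuracy"].append(val_acc)
        if verbose:
            msg = f"epoch {epoch:3d}  loss {history['loss'][-1]:.4f}  acc {history['accuracy'][-1]:.3f}"
            if x_val is not None:
                msg += f"  val_acc {history['val_accuracy'][-1]:.3f}"
            print(msg)
    if x_val is None:
        del history["val_accuracy"]
    return history


def evaluate(model: MVCNNClassifier, x: np.ndarray, y: np.ndarray):
    """Accuracy and confusion matrix on a labelled set.

    Returns (accuracy, C) where C[i, j] counts true class i predicted as
    class j; row sums equal the per-class test counts.
    """
    if len(x) == 0:
        raise ValueError("empty evaluation set")
    y = np.asarray(y)
    k = model.spec.n_classes
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels outside [0, {k}) found in evaluation set")
    pred = model.predict(x)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y, pred), 1)
    accuracy = float(np.trace(cm) / cm.sum())
    return accuracy, cm


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(model: MVCNNClassifier, path) -> None:
    """Architecture spec + weights + label names in one .npz."""
    arrays = {
        f"param_{i}": layer.params[k] for i, (layer, k) in enumerate(model.param_items())
    }
    meta = {"spec": asdict(model.spec), "labels": list(model.spec.labels)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MVCNNClassifier:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec_d = meta["spec"]
    spec_d["head"] = tuple(spec_d["head"])
    spec = ModelSpec(**spec_d)
    model = MVCNNClassifier(spec, rng=np.random.default_rng(0))
    for i, (layer, k) in enumerate(model.param_items()):
        layer.params[k] = data[f"param_{i}"]
    return model
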