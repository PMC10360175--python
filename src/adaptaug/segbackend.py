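"""Pluggable segmentation backend with snapshot/restore, pre-train, fine-tune,
predict and evaluate.

The framework treats the segmentation model as an opaque verifier f(x; θ):
it is pre-trained once on the original training images, snapshotted, and at
every augmentation step the snapshot is restored and briefly fine-tuned on
the union of the original and the augmented images; the evaluation on a fixed
test set produces the reward signal.

The default backend, ``surrogate``, is a pixel-wise logistic classifier over
quadratic RGB colour features, trained by full-batch gradient descent on a
class-balanced pixel sample.  It is deterministic under a seed, trains in
well under a second on 64×64 images, and is sufficient because the synthetic
scenes are colour-separable.  A ``deeplabv3plus`` adapter slot is registered
but not implemented; heavy encoder–decoder networks are out of scope here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .data import ImageVector
from .metrics import (DiceScore, MetricSet, ConfusionCounts, compute_metrics,
                      confusion_counts, dice_ratio, image_iou)

__all__ = [
    "TrainConfig",
    "SurrogateModel",
    "available_backends",
    "pretrain",
    "finetune",
    "predict",
    "evaluate",
    "snapshot",
    "restore",
]

SNAPSHOT_VERSION = 1
_BACKENDS = ("surrogate", "deeplabv3plus")


def available_backends() -> tuple[str, ...]:
    """Registered backend names (``deeplabv3plus`` is a declared slot only)."""
    return _BACKENDS


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for a segmentation backend.

    ``target`` selects which label the model learns (rust spots or whole
    leaf).  ``pixels_per_class`` caps the per-image, per-class pixel sample
    used to build the class-balanced training matrix.  ``epochs`` may be 0
    for a fine-tune, which then returns an unchanged copy of the model.
    """

    epochs: int = 300
    learning_rate: float = 2.0
    batch_size: int = 0          # 0 = full batch
    pixels_per_class: int = 256
    seed: int = 0
    target: str = "rust"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.target not in ("rust", "leaf"):
            raise ValueError(f"target must be 'rust' or 'leaf', got {self.target!r}")


N_FEATURES = 9  # r, g, b, r², g², b², rg, rb, gb


def _pixel_features(image: np.ndarray) -> np.ndarray:
    """(H*W, 9) quadratic colour features in [0, 1] per pixel."""
    x = image.reshape(-1, 3).astype(float) / 255.0
    r, g, b = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack([r, g, b, r * r, g * g, b * b, r * g, r * b, g * b])


@dataclass(frozen=True)
class SurrogateModel:
    """Pixel-wise logistic segmenter: p(foreground) = σ(w·φ(rgb) + b)."""

    weights: np.ndarray
    bias: float
    target: str
    arch_id: str = "surrogate"
    train_log: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_FEATURES,):
            raise ValueError(f"weights must have shape ({N_FEATURES},)")
        object.__setattr__(self, "weights", w)


def _sample_pixels(train_set: ImageVector, target: str, per_class: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced pixel sample across a set of labelled images."""
    feats, labels = [], []
    for item in train_set:
        phi = _pixel_features(item.image)
        y = item.label(target).ravel()
        for cls in (0, 1):
            idx = np.nonzero(y == cls)[0]
            if idx.size == 0:
                continue
            if idx.size > per_class:
                idx = rng.choice(idx, size=per_class, replace=False)
            feats.append(phi[idx])
            labels.append(np.full(idx.size, cls, dtype=float))
    if not feats:
        raise ValueError("no pixels to train on")
    return np.concatenate(feats), np.concatenate(labels)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _gd_train(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
              cfg: TrainConfig) -> tuple[np.ndarray, float, list]:
    """Full-batch gradient descent on mean logistic loss; returns the log."""
    log = []
    for epoch in range(cfg.epochs):
        p = _sigmoid(X @ w + b)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        err = p - y
        grad_w = X.T @ err / len(y)
        grad_b = float(err.mean())
        w = w - cfg.learning_rate * grad_w
        b = b - cfg.learning_rate * grad_b
        log.append((epoch, loss))
    return w, b, log


def _check_arch(arch_id: str) -> None:
    if arch_id not in _BACKENDS:
        raise ValueError(f"unknown backend {arch_id!r}; known: {_BACKENDS}")
    if arch_id == "deeplabv3plus":
        raise NotImplementedError(
            "the deeplabv3plus adapter slot is declared but not implemented")


def pretrain(backend: str, train_set: ImageVector, test_set: ImageVector,
             cfg: TrainConfig) -> tuple[SurrogateModel, list[dict]]:
    """Train a fresh model on ``train_set``; log per-epoch loss and test metrics.

    Returns the trained model and a history of
    ``{"epoch", "loss", "metrics": MetricSet}`` records.
    """
    _check_arch(backend)
    if len(train_set) == 0 or len(test_set) == 0:
        raise ValueError("train and test sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    X, y = _sample_pixels(train_set, cfg.target, cfg.pixels_per_class, rng)
    w = np.zeros(N_FEATURES)
    b = 0.0
    w, b, log = _gd_train(w, b, X, y, cfg)
    model = SurrogateModel(weights=w, bias=b, target=cfg.target,
                           train_log=tuple(log))
    history = []
    for epoch, loss in log:
        history.append({"epoch": epoch, "loss": loss})
    if history:
        _, mset, _ = evaluate(model, test_set, cfg.target)
        history[-1]["metrics"] = mset
    return model, history


def finetune(model: SurrogateModel, retrain_set: ImageVector,
             cfg: TrainConfig) -> SurrogateModel:
    """Continue training on a new set; returns a NEW model, input untouched."""
    if len(retrain_set) == 0:
        raise ValueError("retrain set must be nonempty")
    if cfg.epochs == 0:
        return replace(model, train_log=model.train_log)
    rng = np.random.default_rng(cfg.seed)
    X, y = _sample_pixels(retrain_set, model.target, cfg.pixels_per_class, rng)
    w, b, log = _gd_train(model.weights.copy(), model.bias, X, y, cfg)
    return SurrogateModel(weights=w, bias=b, target=model.target,
                          train_log=model.train_log + tuple(log))


def predict(model: SurrogateModel, image: np.ndarray) -> np.ndarray:
    """Binary mask of the model's foreground class, same H×W as the image."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {image.shape}")
    phi = _pixel_features(image)
    p = _sigmoid(phi @ model.weights + model.bias)
    return (p > 0.5).astype(np.uint8).reshape(image.shape[:2])


def evaluate(model: SurrogateModel, test_set: ImageVector, target: str = "rust"
             ) -> tuple[list[float], MetricSet, DiceScore]:
    """Per-image IoUs (test-set order), pooled metrics, and the Dice ratio."""
    if len(test_set) == 0:
        raise ValueError("test set must be nonempty")
    ious = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for item in test_set:
        truth = item.label(target)
        pred = predict(model, item.image)
        ious.append(image_iou(pred, truth))
        pooled = pooled + confusion_counts(pred, truth)
    return ious, compute_metrics(pooled), dice_ratio(ious)


def snapshot(model: SurrogateModel) -> bytes:
    """Serialize a model to a versioned JSON blob (bit-exact round trip)."""
    payload = {
        "version": SNAPSHOT_VERSION,
        "arch_id": model.arch_id,
        "target": model.target,
        # hex floats preserve every bit across the round trip
        "weights": [v.hex() for v in model.weights],
        "bias": float(model.bias).hex(),
    }
    return json.dumps(payload).encode()


def restore(blob: bytes) -> SurrogateModel:
    """Rebuild a model from a snapshot blob; refuses mismatched backends."""
    try:
        payload = json.loads(blob.decode())
        version = payload["version"]
        arch_id = payload["arch_id"]
        weights = np.array([float.fromhex(v) for v in payload["weights"]])
        bias = float.fromhex(payload["bias"])
        target = payload["target"]
    except (ValueError, KeyError, TypeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt snapshot blob: {exc}") from exc
    if version != SNAPSHOT_VERSION:
        raise ValueError(f"unsupported snapshot version {version}")
    if arch_id != "surrogate":
        raise ValueError(f"snapshot arch_id {arch_id!r} does not match 'surrogate'")
    return SurrogateModel(weights=weights, bias=bias, target=target)
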