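"""AlexNet-style CNN classification pipeline.

Covers the classification half of the pipeline: stratified dataset
splitting, architecture presets, seeded SGD training and prediction.
Two presets are provided:

``alexnet``
    The classic 5-convolution-stage network (227x227 input, 96/256/384/
    384/256 feature maps, two 4096-wide hidden dense layers with dropout).
``small``
    A 3-convolution-stage reduction (64x64 input) with the same design
    grammar, sized for CPU-scale experiments.

Images entering the classifier are resized to the preset's native input
side and scaled to [-1, 1]; the loss is categorical cross-entropy
minimized by SGD with momentum 0.9 (configurable).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

__all__ = [
    "DEFAULT_CLASSES",
    "LabeledDataset",
    "TrainConfig",
    "ModelSpec",
    "split_dataset",
    "build_model",
    "CNNClassifier",
    "train",
    "predict",
    "save_model",
    "load_model",
    "export_history",
]

DEFAULT_CLASSES = ("broccoli", "carrot", "potato", "radish")


@dataclass
class LabeledDataset:
    """Images with class labels drawn from an ordered label set."""

    images: list[np.ndarray]
    labels: list[str]
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            [self.images[i] for i in indices],
            [self.labels[i] for i in indices],
            self.classes,
        )

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the codec study setup)."""

    optimizer: str = "sgd"
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.4
    learning_rate: float = 0.001
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() != "sgd":
            raise ValueError(f"unsupported optimizer: {self.optimizer}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified train/validation/test split.

    Per-class allocation uses largest-remainder rounding, so each split's
    class proportions match the requested fractions within one item, the
    splits are disjoint and their union is the input.  Deterministic for a
    given seed.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be three positive values, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {sum(fractions)}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    labels = np.asarray(ds.labels)
    for cls in ds.classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise ValueError(
                f"class {cls!r} has {idx.size} items, fewer than the 3 splits"
            )
        rng.shuffle(idx)
        exact = np.array(fractions) * idx.size
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for j in np.argsort(-remainder)[: idx.size - counts.sum()]:
            counts[j] += 1
        bounds = np.cumsum(counts)
        parts[0].extend(idx[: bounds[0]])
        parts[1].extend(idx[bounds[0] : bounds[1]])
        parts[2].extend(idx[bounds[1] :])
    return tuple(ds.subset(sorted(p)) for p in parts)


@dataclass
class ModelSpec:
    """Architecture description; instantiated lazily by the classifier."""

    preset: str
    input_size: int
    num_classes: int
    dropout: float
    stages: list[str] = field(default_factory=list)


_PRESETS = {"small": 64, "alexnet": 227}


def build_model(
    num_classes: int, dropout: float = 0.4, preset: str = "small"
) -> ModelSpec:
    """Return the architecture spec for a preset and class count."""
    if num_classes < 2:
        raise ValueError(f"need at least 2 classes, got {num_classes}")
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    stages = (
        [
            "conv 3->96 k11 s4", "relu", "pool k3 s2",
            "conv 96->256 k5 p2", "relu", "pool k3 s2",
            "conv 256->384 k3 p1", "relu",
            "conv 384->384 k3 p1", "relu",
            "conv 384->256 k3 p1", "relu", "pool k3 s2",
            "flatten", "dense 9216->4096", "relu", f"dropout {dropout}",
            "dense 4096->4096", "relu", f"dropout {dropout}",
            f"dense 4096->{num_classes}",
        ]
        if preset == "alexnet"
        else [
            "conv 3->8 k3 p1", "relu", "pool k2 s2",
            "conv 8->16 k3 p1", "relu", "pool k2 s2",
            "conv 16->32 k3 p1", "relu", "pool k2 s2",
            "flatten", "dense 2048->128", "relu", f"dropout {dropout}",
            "dense 128->64", "relu", f"dropout {dropout}",
            f"dense 64->{num_classes}",
        ]
    )
    return ModelSpec(preset, _PRESETS[preset], num_classes, dropout, stages)


def _instantiate(spec: ModelSpec, rng: np.random.Generator) -> nn.Network:
    d, c = spec.dropout, spec.num_classes
    if spec.preset == "alexnet":
        layers = [
            nn.Conv2D(3, 96, 11, stride=4, rng=rng), nn.ReLU(), nn.MaxPool(3, 2),
            nn.Conv2D(96, 256, 5, pad=2, rng=rng), nn.ReLU(), nn.MaxPool(3, 2),
            nn.Conv2D(256, 384, 3, pad=1, rng=rng), nn.ReLU(),
            nn.Conv2D(384, 384, 3, pad=1, rng=rng), nn.ReLU(),
            nn.Conv2D(384, 256, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool(3, 2),
            nn.Flatten(),
            nn.Dense(256 * 6 * 6, 4096, rng=rng), nn.ReLU(), nn.Dropout(d),
            nn.Dense(4096, 4096, rng=rng), nn.ReLU(), nn.Dropout(d),
            nn.Dense(4096, c, rng=rng),
        ]
    else:
        layers = [
            nn.Conv2D(3, 8, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool(2),
            nn.Conv2D(8, 16, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool(2),
            nn.Conv2D(16, 32, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool(2),
            nn.Flatten(),
            nn.Dense(32 * 8 * 8, 128, rng=rng), nn.ReLU(), nn.Dropout(d),
            nn.Dense(128, 64, rng=rng), nn.ReLU(), nn.Dropout(d),
            nn.Dense(64, c, rng=rng),
        ]
    return nn.Network(layers)


def _prepare_images(images, size: int) -> np.ndarray:
    """Resize to the network input side and scale to [-1, 1], NCHW."""
    out = np.empty((len(images), 3, size, size), dtype=nn.DTYPE)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"image {i} has shape {arr.shape}, expected HxWx3")
        if arr.shape[:2] != (size, size):
            arr = np.asarray(
                Image.fromarray(arr.astype(np.uint8)).resize(
                    (size, size), Image.BILINEAR
                )
            )
        out[i] = (arr.astype(float).transpose(2, 0, 1) - 127.5) / 127.5
    return out


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Seeded CNN image classifier with sklearn fit/predict semantics.

    Parameters
    ----------
    preset : {"small", "alexnet"}
        Architecture preset; sets the native input side (64 or 227).
    epochs, batch_size, learning_rate, momentum, dropout, seed
        SGD training hyperparameters.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class labels in fitting order.
    spec_ : ModelSpec actually instantiated.
    network_ : the underlying numpy network.
    history_ : list of per-epoch dicts (train/val accuracy and loss).
    """

    def __init__(
        self,
        preset: str = "small",
        epochs: int = 100,
        batch_size: int = 64,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        dropout: float = 0.4,
        seed: int = 0,
    ) -> None:
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout = dropout
        self.seed = seed

    def fit(self, X, y, validation_data=None) -> "CNNClassifier":
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to fit")
        self.spec_ = build_model(self.classes_.size, self.dropout, self.preset)
        rng = np.random.default_rng(self.seed)
        self.network_ = _instantiate(self.spec_, rng)
        xb_all = _prepare_images(X, self.spec_.input_size)

        val = None
        if validation_data is not None:
            xv, yv = validation_data
            lookup = {c: i for i, c in enumerate(self.classes_)}
            try:
                yv_idx = np.array([lookup[v] for v in yv])
            except KeyError as err:
                raise ValueError(f"validation label outside classes: {err}") from err
            val = (_prepare_images(xv, self.spec_.input_size), yv_idx)

        opt = nn.SGD(self.network_.params, lr=self.learning_rate,
                     momentum=self.momentum)
        n = len(X)
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                logits = self.network_.forward(xb_all[batch], train=True, rng=rng)
                loss, grad = nn.softmax_cross_entropy(logits, y_idx[batch])
                self.network_.backward(grad)
                opt.step(self.network_.grads)
                losses.append(loss * batch.size)
                correct += int((logits.argmax(axis=1) == y_idx[batch]).sum())
            record = {
                "epoch": epoch + 1,
                "train_loss": float(np.sum(losses) / n),
                "train_acc": correct / n,
            }
            if val is not None:
                vlogits = self._forward_batched(val[0])
                vloss, _ = nn.softmax_cross_entropy(vlogits, val[1])
                record["val_loss"] = vloss
                record["val_acc"] = float(
                    (vlogits.argmax(axis=1) == val[1]).mean()
                )
            self.history_.append(record)
        return self

    def _forward_batched(self, x: np.ndarray, chunk: int = 128) -> np.ndarray:
        outs = [
            self.network_.forward(x[i : i + chunk], train=False)
            for i in range(0, len(x), chunk)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        xb = _prepare_images(X, self.spec_.input_size)
        return nn.softmax(self._forward_batched(xb))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")


def train(
    train_set: LabeledDataset,
    val_set: LabeledDataset | None = None,
    config: TrainConfig | None = None,
    preset: str = "small",
) -> CNNClassifier:
    """Fit a classifier on a labeled dataset (thin estimator wrapper)."""
    config = config or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    clf = CNNClassifier(
        preset=preset,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        dropout=config.dropout,
        seed=config.seed,
    )
    val = (val_set.images, val_set.labels) if val_set and len(val_set) else None
    return clf.fit(train_set.images, train_set.labels, validation_data=val)


def predict(model: CNNClassifier, images) -> np.ndarray:
    """Predicted labels for a batch of images (order preserving)."""
    return model.predict(images)


def save_model(model: CNNClassifier, path) -> None:
    """Persist a fitted classifier as an .npz checkpoint."""
    model._check_fitted()
    meta = dict(
        preset=model.preset, epochs=model.epochs, batch_size=model.batch_size,
        learning_rate=model.learning_rate, momentum=model.momentum,
        dropout=model.dropout, seed=model.seed,
        classes=list(map(str, model.classes_)),
        history=model.history_,
    )
    arrays = {f"w{i}": w for i, w in enumerate(model.network_.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> CNNClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    clf = CNNClassifier(
        preset=meta["preset"], epochs=meta["epochs"],
        batch_size=meta["batch_size"], learning_rate=meta["learning_rate"],
        momentum=meta["momentum"], dropout=meta["dropout"], seed=meta["seed"],
    )
    clf.classes_ = np.array(meta["classes"])
    clf.spec_ = build_model(clf.classes_.size, clf.dropout, clf.preset)
    clf.network_ = _instantiate(clf.spec_, np.random.default_rng(0))
    clf.network_.set_weights(weights)
    clf.history_ = meta["history"]
    return clf


def export_history(model: CNNClassifier, path) -> None:
    """Write the per-epoch training history as CSV."""
    model._check_fitted()
    cols = ["epoch", "train_acc", "val_acc", "train_loss", "val_loss"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        for row in model.history_:
            writer.writerow({c: row.get(c, "") for c in cols})


def load_image_folder(root, classes=None) -> LabeledDataset:
    """Read a `<root>/<class>/<index>.png` tree into a LabeledDataset."""
    root = Path(root)
    dirs = sorted(p.name for p in root.iterdir() if p.is_dir())
    classes = tuple(classes) if classes is not None and len(classes) else tuple(dirs)
    images, labels = [], []
    for cls in classes:
        for f in sorted((root / cls).glob("*")):
            if f.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                images.append(np.asarray(Image.open(f).convert("RGB")))
                labels.append(cls)
    return LabeledDataset(images, labels, classes)
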