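"""Training, stratified cross-validation and confusion analysis.

The network is trained with mini-batch stochastic gradient descent with
momentum; the learning rate decays by a factor of 0.1 every third of
the epoch budget.  Cross-validation is stratified by class and seeded;
fold assignment is order-independent (cells are sorted by id before
shuffling).  Confusion matrices follow the convention of coloring by
column sums, so the normalized diagonal reads as per-class precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .architecture import ArchitectureConfig, DeepFlowNetwork, build_deepflow
from .data import CellImageSet
from .errors import (
    ConfigurationError,
    StratificationError,
    TrainingDivergedError,
    ValidationError,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ConfusionMatrix",
    "FoldResults",
    "train",
    "cross_validate",
    "confusion",
    "merge_labels",
    "DeepFlowClassifier",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 10
    lr_decay: float = 0.1  # multiplicative drop applied every epochs//3
    weight_decay: float = 1e-4
    class_weighting: str = "none"  # "none" | "inverse-frequency"
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not (0 <= self.momentum < 1):
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be nonnegative")
        if self.class_weighting not in ("none", "inverse-frequency"):
            raise ConfigurationError(
                f"unknown class_weighting {self.class_weighting!r}"
            )


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def _class_weights(labels: np.ndarray, k: int, mode: str) -> np.ndarray | None:
    if mode == "none":
        return None
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    w = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    return w * (counts > 0).sum() / w.sum()  # mean weight 1 over present classes


def train(network: DeepFlowNetwork, train_set: CellImageSet,
          config: TrainConfig) -> TrainHistory:
    """SGD training; returns the per-epoch loss/accuracy history.

    Deterministic under ``config.seed``: batch order is the only
    randomness.  Aborts with :class:`TrainingDivergedError` on a
    non-finite loss.
    """
    x = train_set.images.astype(np.float32)
    y = train_set.labels
    k = network.config.n_classes
    weights = _class_weights(y, k, config.class_weighting)
    opt = nn.SGD(network.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    decay_every = config.epochs // 3  # drops at 1/3 and 2/3 of the budget
    for epoch in range(config.epochs):
        steps = 0 if decay_every == 0 else min(epoch // decay_every, 2)
        opt.lr = config.learning_rate * config.lr_decay ** steps
        order = rng.permutation(len(x))
        total_loss, total_correct, n_seen = 0.0, 0, 0
        for b, start in enumerate(range(0, len(x), config.batch_size)):
            idx = order[start : start + config.batch_size]
            logits = network.forward(x[idx], train=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(
                logits, y[idx], class_weights=weights
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch=epoch, batch=b, lr=opt.lr)
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            total_loss += loss * len(idx)
            total_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            n_seen += len(idx)
        history.loss.append(total_loss / n_seen)
        history.accuracy.append(total_correct / n_seen)
        history.lr.append(opt.lr)
    return history


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray  # (K, K) nonnegative ints
    label_names: list[str]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / max(self.n, 1)

    def column_normalized(self) -> np.ndarray:
        """Counts normalized to column sums; empty columns become zeros.

        The diagonal of this matrix is per-class precision.
        """
        sums = self.counts.sum(axis=0, keepdims=True).astype(np.float64)
        out = np.divide(self.counts, sums, out=np.zeros_like(self.counts, dtype=np.float64),
                        where=sums > 0)
        return out

    def precision(self) -> np.ndarray:
        return np.diag(self.column_normalized())

    def sensitivity(self) -> np.ndarray:
        sums = self.counts.sum(axis=1).astype(np.float64)
        diag = np.diag(self.counts).astype(np.float64)
        return np.divide(diag, sums, out=np.zeros_like(diag), where=sums > 0)

    def merge(self, mapping: dict[str, str]) -> "ConfusionMatrix":
        """Merge classes; e.g. {"G1": "interphase", "S": "interphase", ...}."""
        new_names = []
        assign = []
        for name in self.label_names:
            tgt = mapping.get(name, name)
            if tgt not in new_names:
                new_names.append(tgt)
            assign.append(new_names.index(tgt))
        k = len(new_names)
        out = np.zeros((k, k), dtype=self.counts.dtype)
        for i in range(len(self.label_names)):
            for j in range(len(self.label_names)):
                out[assign[i], assign[j]] += self.counts[i, j]
        return ConfusionMatrix(counts=out, label_names=new_names)


def confusion(y_true, y_pred, k: int,
              label_names: list[str] | None = None) -> ConfusionMatrix:
    """counts[i, j] = number of cells with true class i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred differ in length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= k):
            raise ValidationError(f"{name} contains labels outside {{0..{k - 1}}}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    if label_names is None:
        label_names = [str(i) for i in range(k)]
    return ConfusionMatrix(counts=counts, label_names=list(label_names))


def merge_labels(labels: np.ndarray, label_names: list[str],
                 mapping: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Apply a class-merge map (e.g. {G1,S,G2} -> interphase) to labels."""
    new_names: list[str] = []
    assign = []
    for name in label_names:
        tgt = mapping.get(name, name)
        if tgt not in new_names:
            new_names.append(tgt)
        assign.append(new_names.index(tgt))
    lut = np.array(assign)
    return lut[np.asarray(labels)], new_names


class DeepFlowClassifier:
    """fit/predict wrapper tying a network to a training configuration."""

    def __init__(self, arch: ArchitectureConfig, config: TrainConfig,
                 seed: int | None = None):
        self.arch = arch
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.network: DeepFlowNetwork | None = None
        self.history: TrainHistory | None = None

    def fit(self, train_set: CellImageSet) -> "DeepFlowClassifier":
        self.network = build_deepflow(self.arch, seed=self.seed)
        cfg = TrainConfig(**{**self.config.__dict__, "seed": self.seed})
        self.history = train(self.network, train_set, cfg)
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict(images)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(images)

    def features(self, images: np.ndarray) -> np.ndarray:
        return self.network.pooled_features(images)


@dataclass
class FoldResults:
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    per_fold_confusion: list[ConfusionMatrix]
    fold_of: np.ndarray  # test-fold index per cell, aligned to the dataset

    def summary(self) -> str:
        return (
            f"{self.mean_accuracy * 100:.2f}% ± "
            f"{self.std_accuracy * 100:.2f}% over {len(self.per_fold_accuracy)} folds"
        )


def cross_validate(
    dataset: CellImageSet,
    arch: ArchitectureConfig | None = None,
    config: TrainConfig | None = None,
    classifier_factory=None,
) -> FoldResults:
    """Seeded, stratified k-fold cross-validation.

    Test folds are disjoint and cover the dataset; every class must have
    at least ``folds`` members.  ``classifier_factory(seed)`` may supply
    any object with ``fit(CellImageSet)`` and ``predict(images)`` — by
    default a :class:`DeepFlowClassifier` built from ``arch``/``config``.
    """
    config = config or TrainConfig()
    k_classes = dataset.n_classes
    counts = dataset.class_counts()
    for ci, c in enumerate(counts):
        if 0 < c < config.folds:
            raise StratificationError(
                f"class {dataset.label_names[ci]!r} has {c} members, "
                f"fewer than folds={config.folds}"
            )
    if classifier_factory is None:
        if arch is None:
            raise ConfigurationError("either arch or classifier_factory is required")

        def classifier_factory(seed):
            return DeepFlowClassifier(arch, config, seed=seed)

    # order-independent fold assignment: sort by cell_id before shuffling
    sort_idx = np.argsort(np.asarray(dataset.cell_ids, dtype=object))
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed % (2**31))
    fold_of = np.full(dataset.n, -1, dtype=int)
    accs, mats = [], []
    for fold, (tr, te) in enumerate(
        skf.split(np.zeros(dataset.n), dataset.labels[sort_idx])
    ):
        train_idx, test_idx = sort_idx[tr], sort_idx[te]
        fold_of[test_idx] = fold
        clf = classifier_factory(config.seed + fold)
        clf.fit(dataset.subset(train_idx))
        y_pred = clf.predict(dataset.images[test_idx])
        y_true = dataset.labels[test_idx]
        cm = confusion(y_true, y_pred, k_classes, dataset.label_names)
        accs.append(cm.accuracy())
        mats.append(cm)
    accs = np.array(accs)
    return FoldResults(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=0)),
        per_fold_confusion=mats,
        fold_of=fold_of,
    )
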