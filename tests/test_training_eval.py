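"""Training loop, cross-validation and confusion-matrix conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepflow import (
    CellImageSet,
    SyntheticConfig,
    TrainConfig,
    build_deepflow,
    confusion,
    cross_validate,
    generate,
    merge_labels,
    train,
)
from deepflow.errors import StratificationError, ValidationError

from conftest import reduced_arch


# ---------------------------------------------------------------- confusion


def test_confusion_identity_predictions():
    cm = confusion([0, 1, 2], [0, 1, 2], 3)
    assert np.array_equal(cm.counts, np.eye(3, dtype=int))
    assert np.allclose(cm.precision(), 1.0)
    assert np.allclose(cm.sensitivity(), 1.0)


def test_confusion_hand_enumerated_case():
    cm = confusion([0, 0, 1], [0, 1, 1], 2)
    assert np.array_equal(cm.counts, [[1, 1], [0, 1]])
    assert cm.precision()[1] == pytest.approx(0.5)
    assert cm.accuracy() == pytest.approx(2 / 3)


def test_confusion_label_out_of_range_rejected():
    with pytest.raises(ValidationError):
        confusion([0, 3], [0, 1], 3)


def test_confusion_random_labels_precision_near_class_prior():
    """With independent uniform predictions, precision ~ true-class prior."""
    rng = np.random.default_rng(0)
    n, k = 10_000, 5
    y_true = rng.integers(0, k, n)
    y_pred = rng.integers(0, k, n)
    cm = confusion(y_true, y_pred, k)
    prior = np.bincount(y_true, minlength=k) / n
    prec = cm.precision()
    col = cm.counts.sum(axis=0)
    for j in range(k):
        sigma = np.sqrt(prior[j] * (1 - prior[j]) / col[j])
        assert abs(prec[j] - prior[j]) <= 3 * sigma


def test_column_normalization_and_empty_columns():
    cm = confusion([0, 0, 1], [0, 0, 0], 3)  # classes 1, 2 never predicted
    norm = cm.column_normalized()
    sums = norm.sum(axis=0)
    assert sums[0] == pytest.approx(1.0)
    assert np.all(norm[:, 1:] == 0.0)  # zeros, not NaN
    assert np.all(np.isfinite(norm))
    assert cm.accuracy() == pytest.approx(np.trace(cm.counts) / 3)


@settings(deadline=None, max_examples=50)
@given(
    labels=st.lists(st.integers(0, 4), min_size=2, max_size=60),
    preds=st.lists(st.integers(0, 4), min_size=2, max_size=60),
)
def test_confusion_commutes_with_class_merging(labels, preds):
    """Five-to-three class merge before counting == merge of the counts."""
    n = min(len(labels), len(preds))
    y_true, y_pred = np.array(labels[:n]), np.array(preds[:n])
    names = ["G1", "S", "G2", "Prophase", "Metaphase"]
    mapping = {"G1": "interphase", "S": "interphase", "G2": "interphase"}
    cm = confusion(y_true, y_pred, 5, names)
    merged_after = cm.merge(mapping)
    yt, new_names = merge_labels(y_true, names, mapping)
    yp, _ = merge_labels(y_pred, names, mapping)
    merged_before = confusion(yt, yp, len(new_names), new_names)
    assert merged_after.label_names == merged_before.label_names
    assert np.array_equal(merged_after.counts, merged_before.counts)


# ---------------------------------------------------------------- training


def test_training_is_seed_deterministic(separable_set):
    ds, _ = separable_set
    cfg = reduced_arch(n_classes=2)
    h1 = train(build_deepflow(cfg, seed=0), ds, TrainConfig(epochs=2, seed=3))
    h2 = train(build_deepflow(cfg, seed=0), ds, TrainConfig(epochs=2, seed=3))
    assert abs(h1.loss[0] - h2.loss[0]) <= 1e-5


def test_single_class_dataset_memorized_after_first_epoch(tiny_set):
    ds, _ = tiny_set
    one = ds.subset(np.where(ds.labels == 0)[0]).select_channels(
        ["brightfield", "darkfield"]
    )
    # keep K=3 head; all labels identical
    cfg = reduced_arch(n_classes=3)
    net = build_deepflow(cfg, seed=0)
    h = train(net, one, TrainConfig(epochs=2, seed=0, learning_rate=0.1))
    # epoch-1 metrics include pre-update batches; after one epoch of
    # updates the single class is fully memorized
    assert h.accuracy[1] == 1.0


def test_divergent_training_aborts_with_diagnostic(separable_set):
    from deepflow.errors import TrainingDivergedError

    ds, _ = separable_set
    cfg = reduced_arch(n_classes=2)
    net = build_deepflow(cfg, seed=0)
    with pytest.raises(TrainingDivergedError) as exc:
        train(net, ds, TrainConfig(epochs=5, seed=0, learning_rate=1e9))
    assert exc.value.epoch >= 0 and exc.value.lr > 0


def test_inverse_frequency_weighting_raises_minority_sensitivity():
    """On 97%-imbalanced data, weighting helps the minority class (5 seeds)."""
    from deepflow import ArchitectureConfig

    arch = ArchitectureConfig(
        input_side=32, input_channels=2, n_classes=2, n_modules=2,
        n_reduction_modules=2, width_schedule=[16, 32], feature_dim=32,
    )
    sens = {"none": [], "inverse-frequency": []}
    for mode in sens:
        for seed in range(5):
            ds, _ = generate(SyntheticConfig(
                n_cells=400, side=32, stage_priors=(0.97, 0, 0, 0, 0, 0, 0.03),
                damaged_fraction=0.0, seed=100 + seed,
            ))
            bf = ds.select_channels(["brightfield", "darkfield"])
            net = build_deepflow(arch, seed=seed)
            train(net, bf, TrainConfig(epochs=9, seed=seed, class_weighting=mode))
            pred = net.predict(bf.images)
            minority = bf.labels == 1
            sens[mode].append(float((pred[minority] == 1).mean()))
    a = np.array(sens["inverse-frequency"])
    b = np.array(sens["none"])
    assert np.all(a >= b)  # paired, per seed
    assert a.mean() > b.mean()


# ---------------------------------------------------------------- CV


class _OracleClassifier:
    """Returns the true labels (looked up by image identity via closure)."""

    def __init__(self, dataset):
        self._images = dataset.images
        self._labels = dataset.labels

    def fit(self, train_set):
        return self

    def predict(self, images):
        idx = [
            int(np.argmin(np.abs(self._images - img).sum(axis=(1, 2, 3))))
            for img in images
        ]
        return self._labels[np.array(idx)]


class _MajorityClassifier:
    def fit(self, train_set):
        self._mode = np.bincount(train_set.labels).argmax()
        return self

    def predict(self, images):
        return np.full(len(images), self._mode)


def _balanced_set(n=100, k=5, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.random((n, 1, 8, 8)).astype(np.float32)
    labels = np.arange(n) % k
    return CellImageSet(
        cell_ids=[f"c{i}" for i in range(n)],
        images=images,
        channel_names=["ch"],
        labels=labels,
        label_names=[str(i) for i in range(k)],
    )


def test_stratified_folds_are_balanced_disjoint_and_covering():
    ds = _balanced_set()
    res = cross_validate(
        ds, config=TrainConfig(folds=5, seed=1),
        classifier_factory=lambda seed: _OracleClassifier(ds),
    )
    assert np.all(res.fold_of >= 0)  # every cell in exactly one test fold
    for f in range(5):
        idx = np.where(res.fold_of == f)[0]
        assert len(idx) == 20
        assert np.all(np.bincount(ds.labels[idx], minlength=5) == 4)


def test_oracle_classifier_scores_perfectly():
    ds = _balanced_set()
    res = cross_validate(
        ds, config=TrainConfig(folds=5, seed=1),
        classifier_factory=lambda seed: _OracleClassifier(ds),
    )
    assert res.mean_accuracy == 1.0
    assert res.std_accuracy == 0.0


def test_majority_classifier_matches_class_prior():
    rng = np.random.default_rng(3)
    n = 500
    labels = (rng.random(n) > 0.8).astype(int)  # prior ~0.8 for class 0
    ds = CellImageSet(
        cell_ids=[f"c{i}" for i in range(n)],
        images=rng.random((n, 1, 8, 8)).astype(np.float32),
        channel_names=["ch"],
        labels=labels,
        label_names=["a", "b"],
    )
    res = cross_validate(
        ds, config=TrainConfig(folds=5, seed=0),
        classifier_factory=lambda seed: _MajorityClassifier(),
    )
    p = (labels == 0).mean()
    assert abs(res.mean_accuracy - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_small_class_raises_stratification_error():
    ds = _balanced_set(n=100, k=5)
    ds.labels[:97] = 0  # class sizes extremely skewed
    with pytest.raises(StratificationError):
        cross_validate(
            ds, config=TrainConfig(folds=5, seed=0),
            classifier_factory=lambda seed: _MajorityClassifier(),
        )


def test_fold_assignment_is_order_independent():
    ds = _balanced_set()
    perm = np.random.default_rng(9).permutation(ds.n)
    shuffled = ds.subset(perm)
    r1 = cross_validate(ds, config=TrainConfig(folds=5, seed=4),
                        classifier_factory=lambda s: _MajorityClassifier())
    r2 = cross_validate(shuffled, config=TrainConfig(folds=5, seed=4),
                        classifier_factory=lambda s: _MajorityClassifier())
    # same cell_id -> same fold, regardless of row order
    for i, cid in enumerate(ds.cell_ids):
        j = shuffled.cell_ids.index(cid)
        assert r1.fold_of[i] == r2.fold_of[j]
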