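"""Feature extraction, embedding, ordering and outlier-cluster detection."""

import numpy as np
import pytest

from deepflow import (
    FeatureMatrix,
    build_deepflow,
    detect_outlier_cluster,
    embed,
    extract_activation_maps,
    extract_features,
    ordering_score,
)
from deepflow.errors import (
    ConfigurationError,
    DegenerateGeometryError,
    ParameterError,
    ValidationError,
)

from conftest import reduced_arch


# ------------------------------------------------------------- features


def test_feature_matrix_is_n_by_336_for_default_model(default_arch, tiny_set):
    from deepflow import SyntheticConfig, generate

    ds, _ = generate(SyntheticConfig(
        n_cells=10, side=64, stage_priors=(0.4, 0.3, 0.3, 0, 0, 0, 0),
        damaged_fraction=0.0, seed=1,
    ))
    bf = ds.select_channels(["brightfield", "darkfield"])
    net = build_deepflow(default_arch, seed=0)
    fm = extract_features(net, bf)
    assert fm.features.shape == (10, 336)
    assert np.all(np.isfinite(fm.features))


def test_duplicated_cells_get_identical_features(tiny_set):
    ds, _ = tiny_set
    bf = ds.select_channels(["brightfield", "darkfield"])
    dup = bf.subset(np.array([0, 1, 0]))
    dup.cell_ids = ["a", "b", "c"]  # keep ids unique
    net = build_deepflow(reduced_arch(), seed=0)
    fm = extract_features(net, dup)
    assert np.abs(fm.features[0] - fm.features[2]).max() <= 1e-6


def test_features_batching_invariant(tiny_set):
    ds, _ = tiny_set
    bf = ds.select_channels(["brightfield", "darkfield"]).subset(np.arange(8))
    net = build_deepflow(reduced_arch(), seed=0)
    batched = extract_features(net, bf, batch_size=8).features
    single = extract_features(net, bf, batch_size=1).features
    assert np.abs(batched - single).max() <= 1e-5


def test_feature_extraction_shape_mismatch_reported(tiny_set):
    ds, _ = tiny_set  # 3 channels, model expects 2
    net = build_deepflow(reduced_arch(), seed=0)
    with pytest.raises(ValidationError, match="2"):
        extract_features(net, ds)


def test_classifier_head_on_features_matches_predict(tiny_set):
    ds, _ = tiny_set
    bf = ds.select_channels(["brightfield", "darkfield"]).subset(np.arange(12))
    net = build_deepflow(reduced_arch(), seed=2)
    probs = net.predict_proba(bf.images)
    feats = extract_features(net, bf).features
    assert np.abs(net.classify_features(feats) - probs).max() <= 1e-5


# ------------------------------------------------------- activation maps


def test_activation_maps_shape_follows_module_depth(tiny_set):
    ds, _ = tiny_set
    bf = ds.select_channels(["brightfield", "darkfield"]).subset(np.arange(3))
    cfg = reduced_arch()
    net = build_deepflow(cfg, seed=0)
    maps = extract_activation_maps(net, bf, module_index=2)
    # two stride-2 reductions: 32 -> 16 -> 8
    assert maps.shape == (3, cfg.width_schedule[1], 8, 8)
    assert maps.min() >= 0.0  # ReLU output
    maps1 = extract_activation_maps(net, bf, module_index=1)
    assert maps1.shape == (3, cfg.width_schedule[0], 16, 16)


def test_activation_maps_index_out_of_range(tiny_set):
    ds, _ = tiny_set
    bf = ds.select_channels(["brightfield", "darkfield"]).subset(np.arange(2))
    net = build_deepflow(reduced_arch(), seed=0)
    with pytest.raises(ConfigurationError, match="range"):
        extract_activation_maps(net, bf, module_index=5)


# ------------------------------------------------------------- embedding


def test_embedding_shape_and_determinism():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(120, 20))
    fm = FeatureMatrix(features=x, cell_ids=[f"c{i}" for i in range(120)])
    e1 = embed(fm, perplexity=15, seed=3, max_iter=300)
    e2 = embed(fm, perplexity=15, seed=3, max_iter=300)
    assert e1.coords.shape == (120, 2)
    assert np.array_equal(e1.coords, e2.coords)


def test_embedding_perplexity_too_large_for_n():
    x = np.random.default_rng(0).normal(size=(50, 5))
    with pytest.raises(ParameterError, match="perplexity"):
        embed(x, perplexity=30)


def test_embedding_separates_well_separated_blobs():
    """Two 10-sigma-apart feature blobs stay linearly separable in 2-D."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(1)
    n = 150
    a = rng.normal(0.0, 1.0, size=(n, 20))
    b = rng.normal(0.0, 1.0, size=(n, 20))
    b[:, 0] += 10.0
    x = np.vstack([a, b])
    y = np.repeat([0, 1], n)
    e = embed(x, perplexity=20, seed=0, max_iter=500)
    acc = LogisticRegression().fit(e.coords, y).score(e.coords, y)
    assert acc >= 0.95


# -------------------------------------------------------------- ordering


def test_ordering_score_is_one_on_a_monotone_line():
    t = np.linspace(0, 1, 200)
    coords = np.stack([3 * t, np.zeros_like(t)], axis=1)
    s = ordering_score(coords, t, seed=0)
    assert s.score == pytest.approx(1.0)
    assert s.p_value <= 0.005


def test_ordering_score_null_on_permuted_covariate():
    rng = np.random.default_rng(2)
    t = np.linspace(0, 1, 500)
    coords = np.stack([t, 0.05 * rng.normal(size=500)], axis=1)
    s = ordering_score(coords, rng.permutation(t), seed=1)
    assert s.score <= max(s.null_band_95, 0.09)


def test_ordering_score_on_noisy_arc():
    """A quarter circle with 5% radial noise is ordered by its parameter."""
    rng = np.random.default_rng(3)
    n = 400
    t = np.sort(rng.uniform(0, 1, n))
    theta = t * np.pi / 2
    r = 1.0 + 0.05 * rng.normal(size=n)
    coords = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    assert ordering_score(coords, t, seed=0).score >= 0.9


def test_ordering_score_invariant_under_rigid_motions():
    rng = np.random.default_rng(4)
    t = rng.uniform(0, 1, 300)
    coords = np.stack([t, 0.3 * t**2 + 0.02 * rng.normal(size=300)], axis=1)
    base = ordering_score(coords, t, seed=0).score
    for angle, flip, shift in [(0.7, False, (2, -1)), (2.2, True, (0, 5)),
                               (-1.1, False, (-3, 0.5))]:
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        if flip:
            rot = rot @ np.array([[1, 0], [0, -1]])
        moved = coords @ rot.T + np.array(shift)
        assert ordering_score(moved, t, seed=0).score == pytest.approx(base, abs=1e-9)


def test_ordering_score_rejects_constant_covariate():
    coords = np.random.default_rng(0).normal(size=(60, 2))
    with pytest.raises(DegenerateGeometryError):
        ordering_score(coords, np.ones(60))


# -------------------------------------------------------------- outliers


def test_single_blob_yields_no_flagged_clusters():
    coords = np.random.default_rng(0).normal(size=(1000, 2))
    rep = detect_outlier_cluster(coords, np.zeros(1000, dtype=int), ["a"])
    assert rep.flagged_clusters == []
    assert not rep.is_abnormal.any()


def test_planted_distant_cluster_is_flagged_with_high_recall():
    rng = np.random.default_rng(1)
    n_bulk, n_out = 970, 30
    bulk = rng.normal(0, 1, size=(n_bulk, 2))
    planted = rng.normal(0, 0.2, size=(n_out, 2)) + np.array([8.0, 8.0])
    coords = np.vstack([bulk, planted])
    labels = np.concatenate([
        rng.integers(0, 3, n_bulk),
        np.repeat([0, 1, 2], n_out // 3),
    ])
    rep = detect_outlier_cluster(coords, labels, ["G1", "S", "G2"])
    assert len(rep.flagged_clusters) == 1
    planted_mask = np.zeros(len(coords), dtype=bool)
    planted_mask[n_bulk:] = True
    recall = rep.is_abnormal[planted_mask].mean()
    assert recall >= 0.9
    comp = rep.flagged_clusters[0]["label_composition"]
    for name in ("G1", "S", "G2"):
        assert comp[name] == pytest.approx(1 / 3, abs=0.1)


def test_outlier_detection_rejects_degenerate_geometry():
    with pytest.raises(DegenerateGeometryError):
        detect_outlier_cluster(np.ones((60, 2)), np.zeros(60, dtype=int), ["a"])
    with pytest.raises(ParameterError):
        detect_outlier_cluster(np.random.default_rng(0).normal(size=(20, 2)),
                               np.zeros(20, dtype=int), ["a"])
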