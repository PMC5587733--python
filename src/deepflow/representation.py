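"""Activation-space analysis: features, embedding, ordering, outliers.

The pooled pre-classifier activations place each cell in a feature
space in which distances read as phenotype similarity.  A nonlinear 2-D
embedding (tSNE with PCA initialisation and a fixed seed) visualizes
this space; the degree to which a continuous covariate (hidden phase
parameter, DNA content) is reconstructed along the embedding's main
axis is quantified by a rank correlation with a permutation test; and
small clusters that detach from the bulk are flagged as candidate
abnormal-cell subpopulations, with their stage-label composition
reported — no abnormality label is ever used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .architecture import DeepFlowNetwork
from .data import CellImageSet
from .errors import (
    DegenerateGeometryError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "FeatureMatrix",
    "Embedding",
    "OrderingScore",
    "OutlierReport",
    "extract_features",
    "extract_activation_maps",
    "embed",
    "ordering_score",
    "detect_outlier_cluster",
]


@dataclass
class FeatureMatrix:
    features: np.ndarray  # (n, d)
    cell_ids: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("non-finite feature values")
        if len(self.cell_ids) != self.features.shape[0]:
            raise ValidationError("cell_ids length != feature rows")


@dataclass
class Embedding:
    coords: np.ndarray  # (n, 2)
    method: str
    perplexity: float
    seed: int
    cell_ids: list[str] = field(default_factory=list)


@dataclass
class OrderingScore:
    score: float  # |Spearman rho| in [0, 1]
    p_value: float
    null_band_95: float  # 95th percentile of the permutation null
    n_permutations: int


@dataclass
class OutlierReport:
    cluster_of: np.ndarray  # (n,) cluster index, -1 = noise
    flagged_clusters: list[dict]  # cluster, size_fraction, label_composition
    is_abnormal: np.ndarray  # (n,) bool
    eps: float


def extract_features(model: DeepFlowNetwork, images: CellImageSet,
                     batch_size: int = 256) -> FeatureMatrix:
    """Pooled pre-classifier activation vectors, one row per cell."""
    c, s = images.n_channels, images.side
    cfg = model.config
    if (c, s) != (cfg.input_channels, cfg.input_side):
        raise ValidationError(
            f"model expects (C, S) = ({cfg.input_channels}, {cfg.input_side}), "
            f"found ({c}, {s})"
        )
    feats = model.pooled_features(images.images, batch_size=batch_size)
    return FeatureMatrix(features=feats, cell_ids=list(images.cell_ids))


def extract_activation_maps(model: DeepFlowNetwork, images: CellImageSet,
                            module_index: int) -> np.ndarray:
    """Per-cell channel maps after dual-path module ``module_index`` (1-based)."""
    return model.activation_maps(images.images, module_index)


def normalize_maps_for_display(maps: np.ndarray) -> np.ndarray:
    """Independently rescale each map to [0, 1] for rendering."""
    lo = maps.min(axis=(-2, -1), keepdims=True)
    hi = maps.max(axis=(-2, -1), keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (maps - lo) / span


def embed(features: FeatureMatrix | np.ndarray, perplexity: float = 30.0,
          seed: int = 0, max_iter: int = 1000) -> Embedding:
    """2-D tSNE of the feature space; deterministic under the seed.

    Initialised from the first two principal components so that runs
    with the same inputs and seed coincide exactly.
    """
    if isinstance(features, FeatureMatrix):
        x, ids = features.features, features.cell_ids
    else:
        x, ids = np.asarray(features), []
    n = x.shape[0]
    if n <= 3 * perplexity:
        raise ParameterError(
            f"n={n} too small for perplexity {perplexity}; "
            f"try perplexity <= {(n - 1) / 3:.1f}"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed % (2**31),
        max_iter=max_iter,
        method="barnes_hut",
    )
    coords = ts.fit_transform(np.asarray(x, dtype=np.float64))
    return Embedding(coords=coords, method="tSNE", perplexity=perplexity,
                     seed=seed, cell_ids=list(ids))


def _principal_axis_projection(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[0]


def ordering_score(embedding: Embedding | np.ndarray, covariate: np.ndarray,
                   n_permutations: int = 999, seed: int = 0) -> OrderingScore:
    """How well a covariate is ordered along the embedding's main axis.

    The 2-D (or higher) coordinates are projected onto their first
    principal axis — a rotation/reflection/translation-invariant 1-D
    pseudo-order — and the score is the absolute Spearman rank
    correlation with the covariate.  Significance comes from a
    permutation test of the covariate.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    cov = np.asarray(covariate, dtype=np.float64)
    if not np.all(np.isfinite(cov)):
        raise ValidationError("covariate contains non-finite values")
    if np.ptp(cov) == 0:
        raise DegenerateGeometryError("constant covariate: ordering undefined")
    if n_permutations < 999:
        raise ParameterError("at least 999 permutations required")
    proj = _principal_axis_projection(coords)
    score = abs(spearmanr(proj, cov).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    pr = rankdata(proj)
    pr = (pr - pr.mean()) / pr.std()
    rc = rankdata(cov)
    rc = (rc - rc.mean()) / rc.std()
    n = len(pr)
    for i in range(n_permutations):
        null[i] = abs(pr @ rng.permutation(rc)) / n
    p = (1 + int((null >= score).sum())) / (n_permutations + 1)
    return OrderingScore(
        score=float(score),
        p_value=float(p),
        null_band_95=float(np.quantile(null, 0.95)),
        n_permutations=n_permutations,
    )


def detect_outlier_cluster(
    embedding: Embedding | np.ndarray,
    labels: np.ndarray,
    label_names: list[str] | None = None,
    max_fraction: float = 0.05,
    min_samples: int | None = None,
    k_neighbors: int = 10,
    eps: float | None = None,
    separation_factor: float = 2.0,
) -> OutlierReport:
    """Flag small clusters separated from the bulk, unsupervised.

    Coordinates are clustered density-based (DBSCAN) with neighborhood
    radius ``eps`` defaulting to the median distance to the
    ``k_neighbors``-th nearest neighbor.  A cluster is flagged when its
    size fraction is at most ``max_fraction`` and none of its points
    lies within ``separation_factor * eps`` of any bulk cluster (every
    cluster too large to be a candidate) — fringe fragments of a
    continuum sit just past ``eps``, a genuinely detached subpopulation
    sits far beyond it.  Each flagged cluster's stage-label composition
    is reported.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = np.asarray(labels)
    n = coords.shape[0]
    if n < 50:
        raise ParameterError(f"need at least 50 points, got {n}")
    if np.ptp(coords, axis=0).max() == 0:
        raise DegenerateGeometryError("all points identical")
    if eps is None:
        nbrs = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
        dists, _ = nbrs.kneighbors(coords)
        eps = float(np.median(dists[:, k_neighbors]))
    if min_samples is None:
        # eps is the median k-th NN distance, so a typical bulk point has
        # ~k neighbors within eps; sparser fringe points become noise
        min_samples = k_neighbors
    cluster_of = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)

    ids, sizes = np.unique(cluster_of[cluster_of >= 0], return_counts=True)
    if len(ids) == 0:
        return OutlierReport(cluster_of=cluster_of, flagged_clusters=[],
                             is_abnormal=np.zeros(n, dtype=bool), eps=eps)
    # the bulk: every cluster too large to be an outlier candidate
    # (falling back to the single largest cluster if all are small)
    large = ids[sizes / n > max_fraction]
    if len(large) == 0:
        large = ids[[np.argmax(sizes)]]
    bulk_mask = np.isin(cluster_of, large)
    bulk_nn = NearestNeighbors(n_neighbors=1).fit(coords[bulk_mask])
    if label_names is None:
        label_names = [str(i) for i in range(int(labels.max()) + 1)]

    flagged = []
    is_abnormal = np.zeros(n, dtype=bool)
    for cid, size in zip(ids, sizes):
        if cid in large or size / n > max_fraction:
            continue
        members = cluster_of == cid
        gap, _ = bulk_nn.kneighbors(coords[members])
        if gap.min() <= separation_factor * eps:
            continue  # touches the bulk: not separated
        comp_counts = np.bincount(labels[members], minlength=len(label_names))
        comp = comp_counts / comp_counts.sum()
        flagged.append(
            {
                "cluster": int(cid),
                "size": int(size),
                "size_fraction": float(size / n),
                "label_composition": {
                    label_names[i]: float(comp[i]) for i in range(len(label_names))
                },
            }
        )
        is_abnormal |= members
    return OutlierReport(cluster_of=cluster_of, flagged_clusters=flagged,
                         is_abnormal=is_abnormal, eps=eps)
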