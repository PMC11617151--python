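"""Multicollinearity-aware permutation importance.

Hyperspectral wavebands (and many vegetation indices) are strongly
collinear, which makes naive per-feature permutation importance
uninterpretable: permuting one of two near-duplicate features barely
moves the model because the other carries the same information.  The
procedure here first groups features by hierarchical Ward clustering of
a Pearson-correlation distance matrix, then repeatedly (i) draws one
random feature per cluster, (ii) fits a random-forest regressor on that
reduced, decorrelated feature set, and (iii) credits each selected
feature's permutation importance (drop in model fit score when the
feature's values are shuffled) to its cluster.  Aggregated over many
iterations, the per-cluster importance distributions show which groups
of wavebands or indices are consistently informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.utils.validation import check_array, check_X_y

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ImportanceResult",
    "correlation_distance",
    "ward_cluster",
    "clustered_permutation_importance",
    "ClusteredPermutationImportance",
    "linkage_to_newick",
]

#: Random-forest settings for importance runs are fixed, not searched,
#: to keep thousands of fits tractable; the leaf-size floor controls
#: in-sample overfitting so permuting a noise feature moves the score
#: little.
RF_IMPORTANCE_PARAMS = {"n_estimators": 60, "min_samples_leaf": 5}


@dataclass
class ClusterAssignment:
    """Feature-to-cluster mapping with the underlying Ward linkage."""

    labels: np.ndarray            # contiguous cluster label per feature
    linkage: np.ndarray           # scipy linkage matrix
    cutoff: float | None
    feature_names: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class ImportanceResult:
    """Per-cluster permutation-importance distributions."""

    samples: pd.DataFrame         # iteration, cluster, feature, importance
    summary: pd.DataFrame         # per-cluster mean and quartiles
    n_iterations: int


def correlation_distance(X: np.ndarray, absolute: bool = True):
    """Pearson-correlation distance matrix d_ij = 1 - |r_ij| (or 1 - r_ij).

    The absolute form treats anti-correlated features as carrying the
    same information, which is what matters for importance grouping.
    Zero-variance features have undefined correlations; they are
    excluded with a warning.  Returns (distance matrix, kept feature
    indices).
    """
    X = check_array(X)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ParameterError("need >= 2 features and >= 3 rows")
    keep = np.flatnonzero(np.std(X, axis=0) > 0)
    if keep.size < X.shape[1]:
        logger.warning("correlation_distance: excluding %d zero-variance feature(s)",
                       X.shape[1] - keep.size)
    if keep.size < 2:
        raise ParameterError("fewer than 2 features with nonzero variance")
    r = np.corrcoef(X[:, keep], rowvar=False)
    d = 1.0 - (np.abs(r) if absolute else r)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding
    np.fill_diagonal(d, 0.0)
    return d, keep


def ward_cluster(
    dist: np.ndarray,
    cutoff: float | None = None,
    n_clusters: int | None = None,
    feature_names: list | None = None,
) -> ClusterAssignment:
    """Agglomerative Ward clustering of a distance matrix.

    Clusters are the connected groups below ``cutoff`` on the dendrogram
    (or exactly ``n_clusters`` by truncating at the appropriate height).
    A nonpositive cutoff degenerates to one cluster per feature (warned).
    Labels are contiguous integers ordered by first feature occurrence.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ParameterError("distance matrix must be square")
    condensed = hierarchy.distance.squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    n = dist.shape[0]
    if n_clusters is not None:
        raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cutoff is not None and cutoff <= 0:
        logger.warning("ward_cluster: cutoff <= 0, every feature its own cluster")
        raw = np.arange(1, n + 1)
    else:
        t = float(cutoff) if cutoff is not None else float(Z[:, 2].max()) + 1.0
        raw = hierarchy.fcluster(Z, t=t, criterion="distance")
    # relabel contiguously in order of first appearance
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        labels[i] = mapping.setdefault(int(lab), len(mapping))
    return ClusterAssignment(labels=labels, linkage=Z, cutoff=cutoff,
                             feature_names=list(feature_names or []))


def clustered_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    clusters: ClusterAssignment,
    n_iterations: int = 10_000,
    seed: int | None = 0,
    rf_params: dict | None = None,
    n_shuffles: int = 5,
    scoring: str = "r2",
) -> ImportanceResult:
    """One-random-feature-per-cluster permutation importance.

    Each iteration draws one feature uniformly at random from every
    cluster, fits a random forest on the reduced feature set, and
    computes each selected feature's permutation importance (mean score
    drop over ``n_shuffles`` shuffles), credited to its cluster.  The
    result carries the full per-cluster distribution over iterations.
    """
    X, y = check_X_y(X, y)
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    if clusters.n_clusters < 2:
        raise ParameterError("need at least 2 clusters")
    if not np.all(np.isfinite(y)):
        raise ParameterError("target must be finite")
    params = dict(RF_IMPORTANCE_PARAMS)
    params.update(rf_params or {})
    rng = np.random.default_rng(seed)
    member_lists = [clusters.members(c) for c in range(clusters.n_clusters)]
    rows = []
    for it in range(n_iterations):
        chosen = np.array([rng.choice(m) for m in member_lists])
        Xi = X[:, chosen]
        model = RandomForestRegressor(
            random_state=int(rng.integers(2**31 - 1)), **params
        ).fit(Xi, y)
        imp = permutation_importance(
            model, Xi, y, n_repeats=n_shuffles, scoring=scoring,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for c, feat, val in zip(range(clusters.n_clusters), chosen,
                                imp.importances_mean):
            name = (clusters.feature_names[feat]
                    if clusters.feature_names else int(feat))
            rows.append((it, c, name, float(val)))
    samples = pd.DataFrame(rows, columns=["iteration", "cluster", "feature", "importance"])
    summary = (
        samples.groupby("cluster")["importance"]
        .agg(mean="mean", q25=lambda s: s.quantile(0.25),
             median="median", q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return ImportanceResult(samples=samples, summary=summary, n_iterations=n_iterations)


class ClusteredPermutationImportance(BaseEstimator):
    """Estimator-shaped wrapper: cluster features, then run the iterated
    one-per-cluster permutation-importance procedure on ``fit``.

    Attributes after fit: ``labels_``, ``linkage_``, ``importances_``
    (long-format samples), ``summary_`` (per-cluster mean/quartiles).
    """

    def __init__(self, cutoff: float | None = 1.0, n_clusters: int | None = None,
                 n_iterations: int = 200, absolute_distance: bool = True,
                 rf_params: dict | None = None, n_shuffles: int = 5,
                 scoring: str = "r2", random_state: int | None = 0):
        self.cutoff = cutoff
        self.n_clusters = n_clusters
        self.n_iterations = n_iterations
        self.absolute_distance = absolute_distance
        self.rf_params = rf_params
        self.n_shuffles = n_shuffles
        self.scoring = scoring
        self.random_state = random_state

    def fit(self, X, y, feature_names: list | None = None):
        X, y = check_X_y(X, y)
        dist, keep = correlation_distance(X, absolute=self.absolute_distance)
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(X.shape[1])])
        kept_names = [names[i] for i in keep]
        clusters = ward_cluster(dist, cutoff=self.cutoff, n_clusters=self.n_clusters,
                                feature_names=kept_names)
        result = clustered_permutation_importance(
            X[:, keep], y, clusters, n_iterations=self.n_iterations,
            seed=self.random_state, rf_params=self.rf_params,
            n_shuffles=self.n_shuffles, scoring=self.scoring,
        )
        self.kept_features_ = keep
        self.clusters_ = clusters
        self.labels_ = clusters.labels
        self.linkage_ = clusters.linkage
        self.importances_ = result.samples
        self.summary_ = result.summary
        return self


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Newick-like nested-text export of a scipy linkage tree."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return walk(tree) + ";"
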