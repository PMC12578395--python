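"""Spatial immune neighborhoods: DBSCAN, bootstrap K selection, phenotyping.

Immune-cell coordinates are clustered with DBSCAN (eps = 85 px ~ 13 um at
0.1507 um/px, minPts = 5) into neighborhoods; neighborhoods with >= 20
members are described by their cell-class proportion vector plus total cell
count, and grouped into recurring phenotypes by K-means.  The number of
phenotypes is chosen by bootstrapping 75% subsamples and locating the knee
of the mean within-cluster sum-of-squared-distance curve; per-phenotype
leave-one-out Z values make the defining features auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans

from renimap.errors import ConfigError

__all__ = [
    "NeighborhoodParams",
    "dbscan_cluster",
    "neighborhood_features",
    "feature_matrix",
    "bootstrap_optimal_k",
    "phenotype_clusters",
    "ClusterPhenotype",
]


@dataclass
class NeighborhoodParams:
    """Hyperparameters of the neighborhood stage (defaults as used on the
    renal CODEX data: eps 85 px, minPts 5, >=20 members, 75%/3000-rep
    bootstrap)."""

    eps_px: float = 85.0
    min_pts: int = 5
    min_members: int = 20
    bootstrap_fraction: float = 0.75
    bootstrap_reps: int = 3000
    k_range: tuple[int, ...] = tuple(range(2, 16))
    seed: int = 0
    all_core: bool = False  # literal "all points are core" reading

    def __post_init__(self):
        if self.eps_px <= 0:
            raise ConfigError("eps must be positive")
        if self.min_pts < 1:
            raise ConfigError("min_pts must be >= 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ConfigError("bootstrap fraction must be in (0, 1]")


def dbscan_cluster(coords: np.ndarray, params: NeighborhoodParams) -> np.ndarray:
    """Standard DBSCAN labels (-1 = noise) over cell positions in pixels.

    A point is core iff its eps-ball (self included) holds >= min_pts points;
    clusters are connected core points plus their border points.  With
    ``all_core`` every point is treated as core (min_samples = 1), so
    clusters become the connected components of the eps-graph.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ConfigError("coords must be a non-empty (n, 2) array")
    min_samples = 1 if params.all_core else params.min_pts
    return DBSCAN(eps=params.eps_px, min_samples=min_samples).fit(coords).labels_


def neighborhood_features(
    labels: np.ndarray,
    cells: pd.DataFrame,
    min_members: int = 20,
    class_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-neighborhood composition features for phenotyping.

    Rows are neighborhoods with >= ``min_members`` cells; columns are the
    per-class proportion of members (over ``class_order``, defaulting to the
    classes observed) plus a raw ``count`` column.  The count column is
    z-scored by :func:`feature_matrix` just before clustering so proportions
    and counts share a scale.
    """
    labels = np.asarray(labels)
    if class_order is None:
        class_order = sorted(cells["class_label"].unique())
    rows = []
    index = []
    for nb in np.unique(labels):
        if nb < 0:
            continue
        members = cells.loc[labels == nb, "class_label"]
        if len(members) < min_members:
            continue
        props = members.value_counts(normalize=True).reindex(class_order, fill_value=0.0)
        rows.append(list(props) + [float(len(members))])
        index.append(int(nb))
    if not rows:
        warnings.warn("no neighborhood reached the member threshold", stacklevel=2)
        return pd.DataFrame(columns=[*class_order, "count"])
    return pd.DataFrame(rows, columns=[*class_order, "count"],
                        index=pd.Index(index, name="neighborhood"))


def feature_matrix(features: pd.DataFrame) -> np.ndarray:
    """Feature array for K-means with the count column z-scored."""
    X = features.to_numpy(dtype=float).copy()
    if X.shape[0] == 0:
        return X
    counts = X[:, -1]
    sd = counts.std()
    X[:, -1] = (counts - counts.mean()) / sd if sd > 0 else 0.0
    return X


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Single Lloyd run with k-means++ (distance-weighted) seeding."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for j in range(1, k):
        tot = d2.sum()
        if tot <= 0:
            centers[j:] = X[rng.integers(n, size=k - j)]
            break
        centers[j] = X[rng.choice(n, p=d2 / tot)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(1))
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = dist.argmin(1)
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centers[j] = X[sel].mean(0)
        if (new_labels == labels).all():
            break
        labels = new_labels
    ssd = float(((X - centers[labels]) ** 2).sum())
    return labels, ssd


def bootstrap_optimal_k(
    features: pd.DataFrame | np.ndarray, params: NeighborhoodParams
) -> dict:
    """Choose the number of neighborhood phenotypes by bootstrap + knee.

    For each K in ``k_range``, the mean (over ``bootstrap_reps`` bootstrap
    draws of a 75% subsample) of the K-means within-cluster SSD is computed;
    the chosen K is the knee of the mean curve — the maximum positive second
    difference of the SSD curve normalized to its first value.  Returns the
    full curves so the choice is auditable, plus a ``low_confidence`` flag
    when no pronounced knee exists (in which case k_star = min(k_range)).
    """
    X = feature_matrix(features) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    ks = sorted(params.k_range)
    n = len(X)
    if n < max(ks):
        raise ConfigError(f"k_range max {max(ks)} exceeds {n} feature rows")
    m = max(1, int(round(params.bootstrap_fraction * n)))
    rng = np.random.default_rng(params.seed)
    ssd = np.zeros((params.bootstrap_reps, len(ks)))
    for rep in range(params.bootstrap_reps):
        sub = X[rng.choice(n, size=m, replace=False)]
        for ki, k in enumerate(ks):
            kk = min(k, len(sub))
            ssd[rep, ki] = _kmeans_once(sub, kk, rng)[1]
    mean_ssd = ssd.mean(0)
    delta = np.diff(mean_ssd)
    norm = mean_ssd / mean_ssd[0] if mean_ssd[0] > 0 else mean_ssd
    d2 = norm[:-2] - 2 * norm[1:-1] + norm[2:]  # second difference at interior K
    low_confidence = True
    k_star = ks[0]
    if d2.size and d2.max() > 0:
        cand = ks[1 + int(np.argmax(d2))]
        # A knee is pronounced only if the curve is nearly flat beyond it:
        # a smooth featureless decay leaves a large fraction of the total
        # drop after any candidate knee.
        i = ks.index(cand)
        total_drop = mean_ssd[0] - mean_ssd[-1]
        remaining = (mean_ssd[i] - mean_ssd[-1]) / total_drop if total_drop > 0 else 1.0
        if remaining <= 0.25:
            k_star = cand
            low_confidence = False
    return {
        "k_star": int(k_star),
        "mean_ssd": pd.Series(mean_ssd, index=ks, name="mean_ssd"),
        "delta_ssd": pd.Series(delta, index=ks[1:], name="delta_ssd"),
        "second_difference": pd.Series(d2, index=ks[1:-1], name="second_difference"),
        "low_confidence": low_confidence,
    }


@dataclass
class ClusterPhenotype:
    """K-means phenotypes of neighborhoods with leave-one-out Z features."""

    k: int
    assignments: pd.Series
    z: pd.DataFrame  # clusters x features; NaN where the outside sd is 0
    inertia: float = field(default=np.nan)


def phenotype_clusters(
    features: pd.DataFrame, k: int, seed: int = 0
) -> ClusterPhenotype:
    """K-means phenotyping plus the leave-one-out Z matrix.

    K-means uses distance-weighted (k-means++) seeding with 10 restarts,
    keeping the best SSD.  For cluster c and feature f,
    ``Z = (mean_in - mean_out) / sd_out`` with the population sd of the
    feature outside the cluster; a zero outside-sd yields a missing Z.
    """
    if k > len(features):
        raise ConfigError(f"k={k} exceeds {len(features)} neighborhoods")
    X = feature_matrix(features)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    assign = pd.Series(km.labels_, index=features.index, name="phenotype")
    raw = features.to_numpy(dtype=float)
    z = np.full((k, features.shape[1]), np.nan)
    for c in range(k):
        inside = km.labels_ == c
        outside = ~inside
        if not outside.any():
            continue
        mu_in = raw[inside].mean(0)
        mu_out = raw[outside].mean(0)
        sd_out = raw[outside].std(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zc = (mu_in - mu_out) / sd_out
        zc[sd_out == 0] = np.nan
        z[c] = zc
    z_df = pd.DataFrame(z, index=pd.RangeIndex(k, name="phenotype"),
                        columns=features.columns)
    return ClusterPhenotype(k=k, assignments=assign, z=z_df, inertia=float(km.inertia_))
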