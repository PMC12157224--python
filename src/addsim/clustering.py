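"""Clustering and cluster validation for compound similarity profiles.

Covers the grouping stages of an additive-screening workflow: binning
(single-linkage threshold grouping at fixed distance cutoffs),
hierarchical clustering over four linkage methods with cophenetic
selection, k-means on (embedded) features, internal validity indices
(connectivity, Dunn, silhouette), column-deletion stability indices
(APN, AD, ADM, FOM), majority-rule selection of the cluster count, and
bootstrap cluster stability via best-match Jaccard coefficients.

Agglomeration, cophenetic distances and tree cuts are delegated to
scipy.cluster.hierarchy (scipy's ``ward`` on a distance matrix is the
Ward.D2 variant: squared-distance Lance–Williams update with heights
reported on the distance scale); k-means to scikit-learn.  The validity
and stability indices are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .similarity import SimilarityMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "BootstrapReport",
    "distance_from_similarity",
    "bin_cluster",
    "hclust",
    "cophenetic_corr",
    "cut_k",
    "internal_indices",
    "stability_indices",
    "kmeans",
    "validation_report",
    "select_k",
    "bootstrap_stability",
    "classical_mds",
    "LINKAGES",
]

LINKAGES = ("single", "average", "complete", "ward.d2")
_SCIPY_METHOD = {"single": "single", "average": "average",
                 "complete": "complete", "ward.d2": "ward"}


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != self.d.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """Merge tree: scipy linkage matrix plus leaf ids and the method name."""
    ids: list
    linkage: str
    z: np.ndarray

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.z]

    def leaf_order(self) -> list:
        return [self.ids[i] for i in _h.leaves_list(self.z)]

    def to_newick(self) -> str:
        """Newick text with merge heights as branch lengths."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}
        trees = {i: str(self.ids[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.z):
            a, b = int(a), int(b)
            la, lb = h - heights[a], h - heights[b]
            trees[n + k] = f"({trees.pop(a)}:{la:g},{trees.pop(b)}:{lb:g})"
            heights[n + k] = h
        (root,) = trees.values()
        return root + ";"


def distance_from_similarity(s: SimilarityMatrix) -> DistanceMatrix:
    """Complement transform d = 1 − s (unit-diagonal similarity assumed)."""
    s.validate()
    return DistanceMatrix(ids=list(s.ids), d=1.0 - s.values)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _as_distance(x, ids=None) -> DistanceMatrix:
    """Coerce features to a z-scored Euclidean DistanceMatrix (pass-through
    for an existing DistanceMatrix)."""
    if isinstance(x, DistanceMatrix):
        return x
    X = np.asarray(x, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    d = squareform(pdist((X - mu) / sd))
    return DistanceMatrix(ids=list(ids) if ids is not None
                          else list(range(len(X))), d=d)


def bin_cluster(x, cutoffs: list[float], ids=None) -> dict[float, dict]:
    """Single-linkage threshold grouping at each cutoff.

    ``x`` is a feature matrix (z-score normalized, Euclidean distances)
    or a :class:`DistanceMatrix`.  A cutoff is a fraction of the maximum
    pairwise distance; two compounds join when their distance is at most
    cutoff × max distance, and clusters are the connected components of
    the resulting graph.  Returns, per cutoff, the sorted cluster-size
    profile and the membership labels.
    """
    if not cutoffs:
        raise ValueError("empty cutoff list")
    dm = _as_distance(x, ids)
    dmax = dm.d.max()
    out = {}
    for cut in cutoffs:
        adj = dm.d <= cut * dmax
        labels = _component_labels(adj)
        sizes = sorted(np.bincount(labels).tolist(), reverse=True)
        out[cut] = {"sizes": sizes, "labels": labels, "ids": dm.ids}
    return out


def _component_labels(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    _, labels = connected_components(csr_matrix(adj), directed=False)
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        out[i] = remap.setdefault(l, len(remap))
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hclust(dm: DistanceMatrix, linkage: str = "ward.d2") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``ward.d2`` follows the squared-distance Ward update with heights
    reported on the distance scale; merge heights are non-decreasing for
    all four supported linkages.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; use one of {LINKAGES}")
    if dm.n < 2:
        raise ValueError("need at least two observations")
    z = _h.linkage(dm.condensed(), method=_SCIPY_METHOD[linkage])
    return Dendrogram(ids=list(dm.ids), linkage=linkage, z=z)


def cophenetic_corr(tree: Dendrogram, dm: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic distances."""
    cond = dm.condensed()
    if np.allclose(cond, cond[0]):
        raise ValueError("degenerate distances: zero variance")
    c, _ = _h.cophenet(tree.z, cond)
    return float(c)


def cut_k(tree: Dendrogram, k: int) -> np.ndarray:
    """Labels from cutting the tree into ``k`` groups.

    Labels are renumbered 0..k−1 by first occurrence, so equal trees give
    identical label vectors regardless of scipy's internal numbering.
    """
    n = len(tree.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = _h.fcluster(tree.z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, l in enumerate(raw):
        out[i] = remap.setdefault(l, len(remap))
    return out


# ---------------------------------------------------------------------------
# Internal validity indices
# ---------------------------------------------------------------------------

def internal_indices(dm: DistanceMatrix, labels, neighbors: int = 10,
                     ) -> tuple[float, float, float]:
    """(connectivity, dunn, silhouette) for a flat clustering.

    Connectivity penalizes, for each observation, nearest neighbors that
    fall outside its cluster with weight 1/rank over the first
    ``neighbors`` ranks (lower is better).  Dunn is the minimum
    between-cluster distance over the maximum cluster diameter (higher is
    better).  Silhouette is the mean of (b−a)/max(a,b) (higher is
    better; singleton silhouette is 0).
    """
    labels = np.asarray(labels)
    d = dm.d
    n = dm.n
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    conn = 0.0
    L = min(neighbors, n - 1)
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        order = order[order != i][:L]
        for rank, j in enumerate(order, start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / rank
    inter = np.inf
    diam = 0.0
    for a in uniq:
        ia = np.where(labels == a)[0]
        if len(ia) > 1:
            diam = max(diam, d[np.ix_(ia, ia)].max())
        for b2 in uniq:
            if b2 <= a:
                continue
            ib = np.where(labels == b2)[0]
            inter = min(inter, d[np.ix_(ia, ib)].min())
    if diam == 0.0:
        warnings.warn("all clusters are singletons or duplicate points; "
                      "Dunn set to 0", stacklevel=2)
        dunn = 0.0
    else:
        dunn = float(inter / diam)
    sil = np.zeros(n)
    for i in range(n):
        same = np.where((labels == labels[i]) & (np.arange(n) != i))[0]
        a_val = d[i, same].mean() if len(same) else 0.0
        b_val = min(d[i, labels == u].mean() for u in uniq if u != labels[i])
        denom = max(a_val, b_val)
        sil[i] = 0.0 if denom == 0 or not len(same) else (b_val - a_val) / denom
    return conn, dunn, float(sil.mean())


# ---------------------------------------------------------------------------
# Column-deletion stability indices
# ---------------------------------------------------------------------------

def _cluster_features(X: np.ndarray, k: int, method: str, linkage: str,
                      seed: int) -> np.ndarray:
    if method == "hclust":
        return cut_k(hclust(_as_distance(X), linkage), k)
    if method == "kmeans":
        return kmeans(X, k, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def stability_indices(X, k: int, method: str = "hclust",
                      linkage: str = "ward.d2", seed: int = 0,
                      ) -> tuple[float, float, float, float]:
    """(apn, ad, adm, fom): column-deletion stability of a clustering.

    For each single-column deletion the data are reclustered and compared
    to the full-data clustering: APN is the average proportion of
    observations not co-clustered with their original companions, AD the
    average distance between observations sharing a cluster under either
    clustering, ADM the average distance between the corresponding
    cluster means, and FOM the root-mean intra-cluster variance of the
    deleted column (all averaged over columns; lower is better for all
    four).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two feature columns")
    if k > n:
        raise ValueError("more clusters than observations")
    full = _cluster_features(X, k, method, linkage, seed)
    d_full = squareform(pdist(X))
    apn_l, ad_l, adm_l, fom_l = [], [], [], []
    for j in range(p):
        part = _cluster_features(np.delete(X, j, axis=1), k,
                                 method, linkage, seed)
        apn_i, ad_i, adm_i = [], [], []
        for i in range(n):
            c0 = np.where(full == full[i])[0]
            c1 = np.where(part == part[i])[0]
            overlap = len(np.intersect1d(c0, c1, assume_unique=True))
            apn_i.append(1.0 - overlap / len(c0))
            ad_i.append(d_full[np.ix_(c0, c1)].mean())
            adm_i.append(float(np.linalg.norm(
                X[c0].mean(axis=0) - X[c1].mean(axis=0))))
        apn_l.append(np.mean(apn_i))
        ad_l.append(np.mean(ad_i))
        adm_l.append(np.mean(adm_i))
        col = X[:, j]
        sse = sum(((col[part == u] - col[part == u].mean()) ** 2).sum()
                  for u in np.unique(part))
        fom_l.append(np.sqrt(sse / n) * np.sqrt(n / max(n - k, 1)))
    return (float(np.mean(apn_l)), float(np.mean(ad_l)),
            float(np.mean(adm_l)), float(np.mean(fom_l)))


# ---------------------------------------------------------------------------
# k-means and embedding
# ---------------------------------------------------------------------------

def classical_mds(dm: DistanceMatrix, dim: int | None = None) -> np.ndarray:
    """Torgerson embedding of a distance matrix (default dim = min(n−1, 10))."""
    n = dm.n
    if dim is None:
        dim = min(n - 1, 10)
    d2 = dm.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dim]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def kmeans(x, k: int, seed: int = 0, restarts: int = 10) -> np.ndarray:
    """Seeded k-means labels (best of ``restarts`` k-means++ starts).

    A :class:`DistanceMatrix` input is embedded by classical
    multidimensional scaling first.
    """
    X = classical_mds(x) if isinstance(x, DistanceMatrix) else np.asarray(
        x, dtype=float)
    if k > len(X):
        raise ValueError("more clusters than observations")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    remap: dict[int, int] = {}
    out = np.empty(len(X), dtype=int)
    for i, l in enumerate(raw):
        out[i] = remap.setdefault(l, len(remap))
    return out


# ---------------------------------------------------------------------------
# Validation report and majority-rule k selection
# ---------------------------------------------------------------------------

#: lower scores are better for these measures, higher for the rest
LOWER_IS_BETTER = {"connectivity", "apn", "ad", "adm", "fom"}
HIGHER_IS_BETTER = {"dunn", "silhouette"}


def validation_report(X, k_range: Iterable[int] = range(2, 7),
                      methods: tuple[str, ...] = ("hclust", "kmeans"),
                      linkage: str = "ward.d2", seed: int = 0,
                      neighbors: int = 10) -> pd.DataFrame:
    """Score clusterings over methods × k on internal and stability measures.

    Returns a long-format frame with columns (method, k, measure, score).
    """
    X = np.asarray(X, dtype=float)
    dm = _as_distance(X)
    rows = []
    for method in methods:
        for k in k_range:
            labels = _cluster_features(X, k, method, linkage, seed)
            if len(np.unique(labels)) < 2:
                continue
            conn, dunn, sil = internal_indices(dm, labels, neighbors)
            apn, ad, adm, fom = stability_indices(
                X, k, method=method, linkage=linkage, seed=seed)
            for measure, score in [("connectivity", conn), ("dunn", dunn),
                                   ("silhouette", sil), ("apn", apn),
                                   ("ad", ad), ("adm", adm), ("fom", fom)]:
                rows.append({"method": method, "k": int(k),
                             "measure": measure, "score": float(score)})
    return pd.DataFrame(rows)


def select_k(report: pd.DataFrame) -> set[int]:
    """Majority-rule candidate cluster counts.

    Each measure votes for its best k (minimum score for connectivity/
    APN/AD/ADM/FOM, maximum for Dunn/silhouette); the k values named by
    the most measures are returned, ties retained.
    """
    if report is None or len(report) == 0:
        raise ValueError("empty validation report")
    votes: list[int] = []
    for measure, grp in report.groupby("measure"):
        scores = grp.groupby("k")["score"].mean()
        best = (scores.idxmin() if measure in LOWER_IS_BETTER
                else scores.idxmax())
        votes.append(int(best))
    counts = pd.Series(votes).value_counts()
    return {int(k) for k, c in counts.items() if c == counts.max()}


# ---------------------------------------------------------------------------
# Bootstrap stability
# ---------------------------------------------------------------------------

@dataclass
class BootstrapReport:
    """Per-cluster bootstrap stability summary."""
    avg_jaccard: list[float]
    dissolution_rate: list[float]
    stability_label: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.stability_label:
            self.stability_label = [_stability_label(j)
                                    for j in self.avg_jaccard]


def _stability_label(avg_j: float) -> str:
    if avg_j < 0.65:
        return "unstable"
    if avg_j > 0.85:
        return "highly stable"
    return "stable"


def bootstrap_stability(dm: DistanceMatrix, k: int, b: int = 100,
                        seed: int = 0, linkage: str = "ward.d2",
                        ) -> BootstrapReport:
    """Bootstrap cluster stability via best-match Jaccard coefficients.

    ``b`` resamples of the observations (with replacement) are
    reclustered on the induced sub-distance-matrix; each original cluster
    is matched to the bootstrap cluster maximizing the Jaccard
    coefficient over the resampled universe.  ``avg_jaccard`` is the mean
    best-match Jaccard per original cluster and ``dissolution_rate`` the
    fraction of resamples where it falls below 0.5.  Labels use the
    0.65 / 0.85 thresholds (below: unstable; above: highly stable).
    """
    if b < 1:
        raise ValueError("need at least one bootstrap resample")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    n = dm.n
    base = cut_k(hclust(dm, linkage), k)
    clusters = [set(np.where(base == u)[0]) for u in np.unique(base)]
    jacc = np.zeros((b, len(clusters)))
    for r in range(b):
        idx = np.sort(rng.integers(0, n, size=n))
        sub = DistanceMatrix(ids=list(idx), d=dm.d[np.ix_(idx, idx)])
        lab = cut_k(hclust(sub, linkage), k)
        present = set(idx.tolist())
        boot_sets = [set(idx[lab == u].tolist()) for u in np.unique(lab)]
        for ci, orig in enumerate(clusters):
            orig_present = orig & present
            best = 0.0
            for bs in boot_sets:
                union = len(orig_present | bs)
                if union:
                    best = max(best, len(orig_present & bs) / union)
            jacc[r, ci] = best
    return BootstrapReport(
        avg_jaccard=[float(x) for x in jacc.mean(axis=0)],
        dissolution_rate=[float(x) for x in (jacc < 0.5).mean(axis=0)])
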