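"""Dimensionality reduction, clustering and internal validation.

The feature matrix is standardized and reduced by PCA; dimensions are
retained by a cumulative-explained-variance rule; the retained scores
are grouped with one of four clustering algorithms (k-means, Ward,
PAM, DIANA) under the Euclidean metric; solutions are compared with
three internal validation measures (mean silhouette, Dunn index,
connectivity) and visualized via classical (Torgerson) MDS.

k-means and Ward delegate to scikit-learn / scipy; PAM and the divisive
DIANA algorithm are implemented here (no maintained implementation in
the scientific Python stack), with deterministic lowest-index
tie-breaking so runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .descriptors import FeatureMatrix

__all__ = [
    "PCAResult", "ContributionTable", "ClusterSolution", "ValidationReport",
    "MDSEmbedding", "run_pca", "variable_contributions", "select_dimensions",
    "cluster", "validate_clusterings", "classical_mds",
]

ALGORITHMS = ("kmeans", "diana", "ward", "pam")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: np.ndarray          # features x dims, orthonormal columns
    scores: np.ndarray            # sites x dims
    feature_names: list[str]
    site_ids: list[str]
    standardized: bool


@dataclass
class ClusterSolution:
    algorithm: str
    k: int
    labels: np.ndarray            # 1..k, relabelled by first occurrence
    site_ids: list[str]
    seed: int | None = None
    centers: np.ndarray | None = None   # centroids (kmeans) or medoids (pam)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.site_ids,
                             "algorithm": self.algorithm,
                             "k": self.k,
                             "cluster": self.labels})


def run_pca(fm: FeatureMatrix, standardize: bool = True) -> PCAResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    The indices mix units (nats, kHz, Gini fractions), so the
    correlation matrix — i.e. z-scored features — is the default.
    Constant columns cannot be standardized and are dropped with a
    warning.
    """
    df = fm.data
    if df.shape[0] < 2:
        raise ValueError("PCA needs at least 2 sites")
    constant = df.nunique() == 1
    if standardize and constant.any():
        dead = list(constant.index[constant])
        warnings.warn(f"dropping constant feature columns: {dead}")
        df = df.drop(columns=dead)
    sd = df.std(ddof=1)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 (non-constant) features")
    X = df.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd.to_numpy()
        C = np.corrcoef(X, rowvar=False)
    else:
        C = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pct = 100.0 * evals / evals.sum()
    return PCAResult(
        eigenvalues=evals,
        explained_variance_pct=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=evecs,
        scores=Xc @ evecs,
        feature_names=list(df.columns),
        site_ids=list(df.index),
        standardized=standardize,
    )


@dataclass
class ContributionTable:
    """Percent contribution of each index (descriptors summed) per dimension."""

    table: pd.DataFrame           # rows = indices, columns = Dim1..DimD

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="index")


def variable_contributions(
    pca: PCAResult, grouping: dict[str, str] | None = None, dims: int = 3
) -> ContributionTable:
    """Squared-loading contributions, aggregated from features to indices.

    contribution(feature, d) = 100 * loading(feature, d)^2 /
    sum_features loading(., d)^2; the index-level entry sums its seven
    descriptors, so every column still sums to 100.
    """
    if grouping is None:
        grouping = {f: f.rsplit("_", 1)[0] for f in pca.feature_names}
    missing = set(pca.feature_names) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover features: {sorted(missing)}")
    dims = min(dims, pca.loadings.shape[1])
    L2 = pca.loadings[:, :dims] ** 2
    contrib = 100.0 * L2 / L2.sum(axis=0)
    df = pd.DataFrame(contrib, index=pca.feature_names,
                      columns=[f"Dim{d + 1}" for d in range(dims)])
    df["__index"] = [grouping[f] for f in pca.feature_names]
    agg = df.groupby("__index", sort=False).sum()
    agg.index.name = "index"
    return ContributionTable(agg)


def select_dimensions(
    pca: PCAResult,
    cum_var_target: float = 78.0,
    eigen_cutoff: float = 1.0,
    rule: str = "cum_var",
) -> int:
    """Number of leading dimensions to retain.

    ``cum_var``: smallest d whose cumulative explained variance meets
    the target; ``eigen``: number of eigenvalues above the cutoff
    (Kaiser rule); ``both``: the larger of the two (union — satisfies
    both criteria's retained sets).
    """
    cum = pca.cumulative_pct
    d_cum = int(np.searchsorted(cum, cum_var_target - 1e-12) + 1)
    if d_cum > cum.size:
        warnings.warn(f"cumulative variance target {cum_var_target}% "
                      "unreachable; retaining all dimensions")
        d_cum = cum.size
    d_eig = int((pca.eigenvalues > eigen_cutoff).sum()) or 1
    if rule == "cum_var":
        return d_cum
    if rule == "eigen":
        return d_eig
    if rule == "both":
        return max(d_cum, d_eig)
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------- clustering

def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw, dtype=int)
    nxt = 1
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = nxt
            nxt += 1
        out[i] = mapping[r]
    return out


def _pam(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids: BUILD + SWAP to convergence.

    Deterministic: BUILD greedily seeds medoids (ties to the lowest
    index); SWAP applies the single best medoid/non-medoid exchange per
    iteration until no exchange lowers the total dissimilarity.
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, -1
        dmin = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dmin - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    medoids = sorted(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                new_cost = D[:, trial].min(axis=1).sum()
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids = sorted(medoids)
            cost = D[:, medoids].min(axis=1).sum()
            improved = True
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, np.array(medoids)


def _diana(X: np.ndarray, k: int) -> np.ndarray:
    """Divisive analysis clustering cut at k clusters.

    Starting from one all-encompassing cluster, repeatedly split the
    cluster with the largest diameter: the observation with the largest
    average dissimilarity to its cluster-mates seeds a splinter group,
    and points migrate to the splinter while their average distance to
    the splinter is smaller than to the remainder.
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        ci = int(np.argmax(diams))     # ties -> lowest cluster index
        if diams[ci] == 0.0:
            # all remaining clusters are point-coincident; split largest
            ci = int(np.argmax([len(c) for c in clusters]))
            if len(clusters[ci]) == 1:
                raise ValueError(f"cannot form {k} clusters from duplicate data")
        members = clusters[ci]
        sub = D[np.ix_(members, members)]
        avg = sub.sum(axis=1) / (len(members) - 1)
        splinter = [int(np.argmax(avg))]   # ties -> lowest index
        rest = [i for i in range(len(members)) if i not in splinter]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            best_diff, best_i = 0.0, None
            for i in rest:
                d_spl = sub[i, splinter].mean()
                d_rest = sub[i, [j for j in rest if j != i]].mean()
                diff = d_rest - d_spl
                if diff > best_diff + 1e-12:
                    best_diff, best_i = diff, i
            if best_i is not None:
                splinter.append(best_i)
                rest.remove(best_i)
                moved = True
        clusters[ci] = [members[i] for i in sorted(rest)]
        clusters.append([members[i] for i in sorted(splinter)])
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(clusters):
        labels[c] = lab
    return labels


def cluster(
    scores: np.ndarray,
    algorithm: str,
    k: int,
    seed: int = 0,
    site_ids: list[str] | None = None,
) -> ClusterSolution:
    """Group sites in PCA-score space with one of the four algorithms.

    k-means uses k-means++ initialization with 25 restarts at a fixed
    seed; Ward cuts the agglomerative dendrogram at k; PAM and DIANA
    are the deterministic implementations above.  Labels are 1..k in
    order of first site occurrence.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} sites")
    if k < 1:
        raise ValueError("k must be >= 1")
    site_ids = site_ids or [f"S{i:02d}" for i in range(n)]
    centers = None
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=25,
                    random_state=seed).fit(X)
        raw, centers = km.labels_, km.cluster_centers_
    elif algorithm == "ward":
        raw = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
    elif algorithm == "pam":
        raw, med = _pam(X, k)
        centers = X[med]
    elif algorithm == "diana":
        raw = _diana(X, k)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {ALGORITHMS}")
    labels = _relabel_first_occurrence(np.asarray(raw))
    return ClusterSolution(algorithm=algorithm, k=k, labels=labels,
                           site_ids=list(site_ids),
                           seed=seed if algorithm == "kmeans" else None,
                           centers=centers)


# ---------------------------------------------------------------- validation

def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    ks = np.unique(labels)
    max_diam = 0.0
    for a in ks:
        idx = np.flatnonzero(labels == a)
        if idx.size > 1:
            max_diam = max(max_diam, D[np.ix_(idx, idx)].max())
    min_sep = np.inf
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            min_sep = min(min_sep, D[np.ix_(ia, ib)].min())
    if max_diam == 0.0:
        return np.inf if np.isfinite(min_sep) else 0.0
    return float(min_sep / max_diam)


def _connectivity(D: np.ndarray, labels: np.ndarray, L: int) -> float:
    """clValid connectivity: sum of 1/j over each point's j-th nearest
    neighbour (j = 1..L) that falls outside the point's cluster.  Lower
    is better; 0 means every point's L nearest neighbours are in-cluster."""
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        nn = [j for j in order if j != i][:L]
        for rank, j in enumerate(nn, start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


@dataclass
class ValidationReport:
    table: pd.DataFrame  # rows (algorithm, k); silhouette, dunn, connectivity

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def validate_clusterings(
    scores: np.ndarray, solutions: list[ClusterSolution], L: int = 5
) -> ValidationReport:
    """Internal validation of one or more cluster solutions."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    D = squareform(pdist(X))
    rows = []
    for sol in solutions:
        lab = sol.labels
        nlab = len(np.unique(lab))
        if 2 <= nlab <= len(lab) - 1:
            sil, degenerate = float(silhouette_score(X, lab)), False
        else:  # all-singleton or single-cluster: silhouette undefined
            sil, degenerate = 0.0, True
        rows.append({
            "algorithm": sol.algorithm, "k": sol.k,
            "silhouette": sil,
            "dunn": _dunn(D, lab),
            "connectivity": _connectivity(D, lab, min(L, len(lab) - 1)),
            "silhouette_degenerate": degenerate,
        })
    return ValidationReport(pd.DataFrame(rows))


# ----------------------------------------------------------------------- MDS

@dataclass
class MDSEmbedding:
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def to_csv(self, path, site_ids=None) -> None:
        df = pd.DataFrame(self.coordinates, columns=["mds1", "mds2"])
        if site_ids is not None:
            df.insert(0, "site_id", site_ids)
        df.to_csv(path, index=False)


def classical_mds(distances: np.ndarray, dims: int = 2) -> MDSEmbedding:
    """Torgerson scaling: embed a distance matrix in ``dims`` dimensions.

    Double-centre -D^2/2, eigendecompose, and scale the top eigenvectors
    by the square root of their (non-negative) eigenvalues.  For true
    Euclidean distances of a ``dims``-dimensional configuration the
    pairwise distances are recovered exactly up to rotation/reflection.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distances must be non-negative with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = np.maximum(evals[:dims], 0.0)
    coords = evecs[:, :dims] * np.sqrt(top)[None, :]
    return MDSEmbedding(coordinates=coords, eigenvalues=evals)
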