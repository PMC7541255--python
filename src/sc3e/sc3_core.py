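"""Self-contained SC3-style consensus clustering engine.

Pipeline per preprocessed matrix: detection-based gene filter -> three cell
distance matrices (euclidean, pearson, spearman) -> two spectral transforms
(PCA of the distance matrix, normalized graph Laplacian) -> k-means over a
grid of embedding dimensions -> co-association consensus matrix ->
complete-linkage cut into k clusters.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.cluster.hierarchy as hierarchy
import scipy.spatial.distance as ssd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from sc3e.preprocess import PreprocessedMatrix

DISTANCE_METRICS = ("euclidean", "pearson", "spearman")
TRANSFORM_KINDS = ("pca", "laplacian")


@dataclass(frozen=True, eq=False)
class ConsensusMatrix:
    """n x n symmetric co-association matrix with entries in [0, 1]."""

    values: np.ndarray
    cell_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        n = len(self.cell_ids)
        if values.shape != (n, n):
            raise ValueError(f"consensus shape {values.shape} vs {n} cell ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("consensus matrix not symmetric")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("consensus entries outside [0, 1]")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("consensus diagonal must be 1")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            self.values, index=list(self.cell_ids), columns=list(self.cell_ids)
        ).to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str) -> "ConsensusMatrix":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, float_precision="round_trip")
        return cls(values=df.to_numpy(dtype=np.float64), cell_ids=[str(c) for c in df.index])


@dataclass(frozen=True, eq=False)
class ClusterLabels:
    """One cluster id in 1..num_clusters per cell."""

    labels: np.ndarray
    num_clusters: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.num_clusters < 1:
            raise ValueError("num_clusters must be >= 1")
        if labels.size and (labels.min() < 1 or labels.max() > self.num_clusters):
            raise ValueError("labels out of range 1..num_clusters")

    @property
    def n_cells(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class SC3Config:
    """Knobs of the consensus engine (SC3-style defaults)."""

    lower_pct: float = 0.06
    upper_pct: float = 0.94
    d_range: tuple = (0.04, 0.07)
    metrics: tuple = DISTANCE_METRICS
    transforms: tuple = TRANSFORM_KINDS
    n_init: int = 10
    max_iter: int = 300


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts.

    Independent of PYTHONHASHSEED, unlike built-in ``hash``.
    """
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def filter_genes(
    P: PreprocessedMatrix, lower_pct: float = 0.06, upper_pct: float = 0.94
) -> PreprocessedMatrix:
    """Drop genes detected in fewer than ``lower_pct * n`` or more than
    ``upper_pct * n`` cells (detection = raw value > 0)."""
    if not (0 <= lower_pct < upper_pct <= 1):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 1")
    n = P.n_cells
    counts = P.detected.sum(axis=1)
    keep = (counts >= lower_pct * n) & (counts <= upper_pct * n)
    if not keep.any():
        raise ValueError(
            "gene filter removed every gene; relax lower_pct/upper_pct "
            f"(currently {lower_pct}/{upper_pct})"
        )
    return replace(
        P,
        values=P.values[keep],
        detected=P.detected[keep],
        gene_ids=tuple(g for g, k in zip(P.gene_ids, keep) if k),
    )


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    # columns = cells; zero-variance columns get distance 1 to everything
    n = values.shape[1]
    sd = values.std(axis=0)
    ok = sd > 0
    D = np.ones((n, n))
    if ok.sum() >= 2:
        r = np.corrcoef(values[:, ok], rowvar=False)
        idx = np.where(ok)[0]
        D[np.ix_(idx, idx)] = 1.0 - r
    np.fill_diagonal(D, 0.0)
    return D


def cell_distances(P: PreprocessedMatrix, metric: str) -> np.ndarray:
    """Pairwise cell-cell distance matrix under one of the three metrics."""
    if P.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if metric == "euclidean":
        D = ssd.squareform(ssd.pdist(P.values.T, metric="euclidean"))
    elif metric == "pearson":
        D = _correlation_distance(P.values)
    elif metric == "spearman":
        ranks = np.apply_along_axis(rankdata, 0, P.values)
        D = _correlation_distance(ranks)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return (D + D.T) / 2.0


def spectral_transform(D: np.ndarray, kind: str, d: int) -> np.ndarray:
    """Embed cells in d dimensions from a distance matrix.

    ``pca``: first d principal components of the (column-centered) distance
    matrix.  ``laplacian``: eigenvectors of the symmetric normalized graph
    Laplacian of the similarity exp(-D / max(D)), ascending eigenvalue.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if d < 1 or d > n:
        raise ValueError(f"need 1 <= d <= n, got d={d}, n={n}")
    if kind == "pca":
        centered = D - D.mean(axis=0, keepdims=True)
        if not np.any(centered):
            raise ValueError("degenerate distance matrix: rank deficient after centering")
        # principal component scores via SVD
        U, svals, _ = np.linalg.svd(centered, full_matrices=False)
        return U[:, :d] * svals[:d]
    if kind == "laplacian":
        dmax = D.max()
        if dmax <= 0:
            raise ValueError("degenerate distance matrix: all distances equal")
        S = np.exp(-D / dmax)
        deg = S.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(deg)
        L = np.eye(n) - (inv_sqrt[:, None] * S * inv_sqrt[None, :])
        _, vecs = scipy.linalg.eigh(L)
        return vecs[:, :d]
    raise ValueError(f"unknown transform kind {kind!r}")


def kmeans_ensemble(
    P: PreprocessedMatrix,
    k: int,
    seed: int,
    config: SC3Config = SC3Config(),
) -> list:
    """Run k-means over the metric x transform x dimension grid.

    Returns one :class:`ClusterLabels` per grid point.  The grid dimensions
    are ``round(d_range * n)`` inclusive; if empty, falls back to a single
    d = min(n - 1, k + 1) with a warning.
    """
    n = P.n_cells
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need more cells than clusters (n={n}, k={k})")
    lo = int(round(config.d_range[0] * n))
    hi = int(round(config.d_range[1] * n))
    d_values = [d for d in range(lo, hi + 1) if 1 <= d <= n - 1]
    if not d_values:
        d_values = [min(n - 1, k + 1)]
        warnings.warn(
            f"d_range {config.d_range} gives no valid dimensions for n={n}; "
            f"falling back to d={d_values[0]}",
            stacklevel=2,
        )
    ensemble = []
    for metric in config.metrics:
        D = cell_distances(P, metric)
        for kind in config.transforms:
            for d in d_values:
                emb = spectral_transform(D, kind, d)
                km = KMeans(
                    n_clusters=k,
                    n_init=config.n_init,
                    max_iter=config.max_iter,
                    random_state=stable_seed(seed, metric, kind, d),
                )
                raw = km.fit_predict(emb)
                ensemble.append(ClusterLabels(labels=raw + 1, num_clusters=k))
    return ensemble


def consensus_from_ensemble(ensemble, cell_ids=None) -> ConsensusMatrix:
    """Co-association matrix: fraction of labelings co-clustering each pair."""
    if not ensemble:
        raise ValueError("empty ensemble")
    n = ensemble[0].n_cells
    if any(lab.n_cells != n for lab in ensemble):
        raise ValueError("labelings cover different numbers of cells")
    acc = np.zeros((n, n))
    for lab in ensemble:
        acc += lab.labels[:, None] == lab.labels[None, :]
    acc /= len(ensemble)
    np.fill_diagonal(acc, 1.0)
    if cell_ids is None:
        cell_ids = [f"cell{i + 1}" for i in range(n)]
    return ConsensusMatrix(values=acc, cell_ids=cell_ids)


def cluster_consensus(C: ConsensusMatrix, k: int) -> ClusterLabels:
    """Complete-linkage cut of 1 - C into k clusters, relabeled 1..k by
    first appearance."""
    n = C.n_cells
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    dist = 1.0 - C.values
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel to consecutive ids by first appearance
    order = {}
    labels = np.empty(n, dtype=np.int64)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order) + 1
        labels[i] = order[r]
    return ClusterLabels(labels=labels, num_clusters=k)


def run_consensus(
    P: PreprocessedMatrix,
    k: int,
    seed: int,
    config: SC3Config = SC3Config(),
):
    """Full engine: gene filter -> ensemble -> consensus -> cut.

    Returns (ConsensusMatrix, ClusterLabels).
    """
    filtered = filter_genes(P, config.lower_pct, config.upper_pct)
    ensemble = kmeans_ensemble(filtered, k, seed, config)
    C = consensus_from_ensemble(ensemble, cell_ids=P.cell_ids)
    T = cluster_consensus(C, k)
    return C, T
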