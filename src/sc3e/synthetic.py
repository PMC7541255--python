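"""Synthetic clustered scRNA-seq fixtures with known labels.

Counts are negative-binomial (variance mu + dispersion * mu^2) around
log-normal baseline gene means, with cluster-specific fold-changes on a
random subset of genes, log-normal library-size variation, optional extra
dropout zeros, and conversion to any of the supported expression units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sc3e.expr_io import ExpressionMatrix, VALID_UNITS
from sc3e.sc3_core import ClusterLabels, ConsensusMatrix


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 60
    n_genes: int = 200
    k_clusters: int = 3
    de_fraction: float = 0.2
    log2_fold_change: float = 2.0
    dispersion: float = 0.1
    dropout_rate: float = 0.0
    library_size_cv: float = 0.1
    units_out: str = "READS"
    gene_length_range: tuple = (500, 5000)
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.k_clusters) < 1:
            raise ValueError("sizes must be >= 1")
        if self.k_clusters > self.n_cells:
            raise ValueError("k_clusters cannot exceed n_cells")
        for name in ("de_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion < 0 or self.library_size_cv < 0:
            raise ValueError("dispersion and library_size_cv must be >= 0")
        if self.units_out not in VALID_UNITS - {"UNKNOWN"}:
            raise ValueError(f"units_out must be one of {sorted(VALID_UNITS - {'UNKNOWN'})}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be a positive interval")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2; Poisson when dispersion == 0."""
    if dispersion == 0:
        return rng.poisson(mean).astype(np.float64)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos]).astype(np.float64)
    return out


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Standard across-column quantile normalization (sort, average, map back)."""
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_rows = x.shape[0]
    row_idx = np.arange(n_rows)
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = row_idx
    mean_quantiles = np.sort(x, axis=0).mean(axis=1)
    return mean_quantiles[ranks]


def simulate_counts(config: SimConfig):
    """Generate (ExpressionMatrix, ClusterLabels) with planted clusters.

    Cells are assigned to clusters in balanced round-robin order.  Each
    cluster up- or down-regulates its own random ``de_fraction`` of genes
    by 2**(+-log2_fold_change).
    """
    rng = np.random.default_rng(config.seed)
    m, n, k = config.n_genes, config.n_cells, config.k_clusters

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=m))
    labels = np.arange(n) % k + 1

    cluster_means = np.tile(base[:, None], (1, k)).astype(np.float64)
    n_de = int(round(config.de_fraction * m))
    for c in range(k):
        de_genes = rng.choice(m, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        cluster_means[de_genes, c] *= 2.0 ** (signs * config.log2_fold_change)

    if config.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(config.library_size_cv**2))
        lib = np.exp(rng.normal(-sigma**2 / 2, sigma, size=n))
    else:
        lib = np.ones(n)

    mean_matrix = cluster_means[:, labels - 1] * lib[None, :]
    counts = _nb_draw(rng, mean_matrix, config.dispersion)

    if config.dropout_rate > 0:
        counts[rng.random(size=counts.shape) < config.dropout_rate] = 0.0

    lengths_kb = (
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=m)
        / 1000.0
    )

    units = config.units_out
    values = counts
    if units in ("CPM", "RPKM", "FPKM", "TPM", "QN"):
        colsum = values.sum(axis=0)
        colsum[colsum == 0] = 1.0
        if units == "CPM":
            values = values / colsum * 1e6
        elif units in ("RPKM", "FPKM"):
            values = values / colsum * 1e6 / lengths_kb[:, None]
        elif units == "TPM":
            per_kb = values / lengths_kb[:, None]
            denom = per_kb.sum(axis=0)
            denom[denom == 0] = 1.0
            values = per_kb / denom * 1e6
        elif units == "QN":
            values = _quantile_normalize(values)

    M = ExpressionMatrix(
        values=values,
        gene_ids=[f"gene{i + 1}" for i in range(m)],
        cell_ids=[f"cell{j + 1}" for j in range(n)],
        units=units,
    )
    return M, ClusterLabels(labels=labels, num_clusters=k)


def simulate_consensus(
    n_cells: int,
    k: int,
    within_mean: float,
    between_mean: float,
    noise_sd: float,
    seed: int,
):
    """Planted block consensus matrix plus its labels.

    Off-diagonal entries are ``within_mean`` inside blocks and
    ``between_mean`` outside, with symmetric truncated Gaussian noise; the
    diagonal is exactly 1.
    """
    if not (0.0 <= between_mean <= within_mean <= 1.0):
        raise ValueError("need 0 <= between_mean <= within_mean <= 1")
    if k < 1 or k > n_cells:
        raise ValueError("need 1 <= k <= n_cells")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_cells) % k + 1
    same = labels[:, None] == labels[None, :]
    C = np.where(same, within_mean, between_mean).astype(np.float64)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n_cells, n_cells))
        noise = (noise + noise.T) / 2.0
        C = C + noise
    C = np.clip(C, 0.0, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    cells = [f"cell{i + 1}" for i in range(n_cells)]
    return (
        ConsensusMatrix(values=C, cell_ids=cells),
        ClusterLabels(labels=labels, num_clusters=k),
    )


def spiked_counts_fixture(
    seed: int, n_cells: int = 45, n_genes: int = 60, k: int = 3, n_spikes: int = 3
):
    """Counts where raw-scale structure is swamped by a few huge-magnitude
    genes uncorrelated with the clusters, so per-gene standardization is
    clearly the better preprocessing.  Returns (ExpressionMatrix, labels).
    """
    cfg = SimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        k_clusters=k,
        de_fraction=0.4,
        log2_fold_change=3.0,
        dispersion=0.05,
        dropout_rate=0.0,
        library_size_cv=0.05,
        units_out="READS",
        seed=seed,
    )
    M, truth = simulate_counts(cfg)
    rng = np.random.default_rng(seed + 10_000)
    values = M.values.copy()
    # overwrite the first genes: enormous cluster-independent magnitude
    for g in range(n_spikes):
        spike = rng.uniform(1e5, 2e5, size=n_cells)
        spike[rng.random(n_cells) < 0.1] = 0.0  # keep it past detection filters
        values[g] = spike
    M2 = ExpressionMatrix(
        values=values, gene_ids=M.gene_ids, cell_ids=M.cell_ids, units="READS"
    )
    return M2, truth
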