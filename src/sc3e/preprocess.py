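"""The four candidate preprocessing transforms.

Each transform maps an :class:`~sc3e.expr_io.ExpressionMatrix` to a
:class:`PreprocessedMatrix` of identical shape.  The matrix carries a
per-gene-per-cell detection mask (raw value > 0) so downstream gene
filtering can operate on the untransformed scale even after z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sc3e.expr_io import ExpressionMatrix

METHODS = ("log", "zscore", "none", "sctransform")

#: floor for the method-of-moments NB dispersion parameter theta
THETA_MIN = 0.01


@dataclass(frozen=True, eq=False)
class PreprocessedMatrix:
    """A transformed genes x cells matrix with provenance.

    ``detected`` records which entries were nonzero in the raw input; the
    consensus engine's gene filter consumes it instead of the (possibly
    signed) transformed values.
    """

    values: np.ndarray
    method: str
    gene_ids: tuple
    cell_ids: tuple
    detected: np.ndarray

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        values = np.asarray(self.values, dtype=np.float64)
        detected = np.asarray(self.detected, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "detected", detected)
        if values.shape != detected.shape:
            raise ValueError("values and detection mask shapes differ")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("id lengths do not match matrix shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _wrap(M: ExpressionMatrix, values: np.ndarray, method: str) -> PreprocessedMatrix:
    return PreprocessedMatrix(
        values=values,
        method=method,
        gene_ids=M.gene_ids,
        cell_ids=M.cell_ids,
        detected=M.values > 0,
    )


def log_transform(M: ExpressionMatrix) -> PreprocessedMatrix:
    """Elementwise log2(x + 1)."""
    return _wrap(M, np.log2(M.values + 1.0), "log")


def zscore_transform(M: ExpressionMatrix, ddof: int = 1) -> PreprocessedMatrix:
    """Per-gene standardization (x - mu_i) / sigma_i.

    Uses the sample (n-1) standard deviation by default.  Rows with zero
    standard deviation map to all-zero rows so the output keeps the input
    dimensions.
    """
    mu = M.values.mean(axis=1, keepdims=True)
    sigma = M.values.std(axis=1, ddof=ddof, keepdims=True)
    out = np.zeros_like(M.values)
    ok = (sigma > 0).ravel()
    out[ok] = (M.values[ok] - mu[ok]) / sigma[ok]
    return _wrap(M, out, "zscore")


def no_transform(M: ExpressionMatrix) -> PreprocessedMatrix:
    """Identity copy."""
    return _wrap(M, M.values.copy(), "none")


def sctransform_like(M: ExpressionMatrix, theta_min: float = THETA_MIN) -> PreprocessedMatrix:
    """Simplified variance-stabilizing transform: NB Pearson residuals.

    For gene i and cell j with library size s_j = sum_i x_ij, the expected
    count under a multinomial-rate model is mu_ij = s_j * g_i where
    g_i = sum_j x_ij / sum_j s_j.  Residuals are

        r_ij = (x_ij - mu_ij) / sqrt(mu_ij + mu_ij^2 / theta_i)

    with a per-gene method-of-moments theta_i (floored at ``theta_min``)
    and clipped to +-sqrt(n_cells).  This is a deliberately simplified
    stand-in for the full regularized NB regression fit; it is exposed
    behind the same interface so a faithful port can be swapped in.
    """
    x = M.values
    s = x.sum(axis=0)  # library sizes
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero expression matrix: library sizes are zero")
    if np.any(s <= 0):
        raise ValueError("cells with zero library size; remove empty cells first")
    g = x.sum(axis=1) / total  # per-gene rate
    mu = np.outer(g, s)

    # method-of-moments overdispersion: E[(x-mu)^2 - mu] = mu^2 / theta
    excess = ((x - mu) ** 2 - mu).sum(axis=1)
    mu_sq = (mu**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_theta = np.where(mu_sq > 0, np.maximum(excess, 0.0) / mu_sq, 0.0)
        theta = np.where(inv_theta > 0, 1.0 / inv_theta, np.inf)
    theta = np.maximum(theta, theta_min)

    denom_sq = mu + mu**2 / theta[:, None]
    out = np.zeros_like(x)
    ok = denom_sq > 0
    out[ok] = (x[ok] - mu[ok]) / np.sqrt(denom_sq[ok])
    clip = np.sqrt(M.n_cells)
    np.clip(out, -clip, clip, out=out)
    return _wrap(M, out, "sctransform")


_TRANSFORMS = {
    "log": log_transform,
    "zscore": zscore_transform,
    "none": no_transform,
    "sctransform": sctransform_like,
}


def apply_transform(M: ExpressionMatrix, method: str) -> PreprocessedMatrix:
    """Dispatch to one of the four transforms by canonical name."""
    try:
        fn = _TRANSFORMS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}") from None
    return fn(M)
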