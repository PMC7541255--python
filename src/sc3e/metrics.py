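"""External clustering-quality metrics.

The adjusted Rand index is computed from the contingency table with exact
integer binomial coefficients, so it stays exact at large cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import pearsonr


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two partitions over the same cells."""

    n_ij: np.ndarray
    a_i: np.ndarray  # row sums
    b_j: np.ndarray  # column sums
    n_total: int

    @classmethod
    def from_labels(cls, A, B) -> "ContingencyTable":
        A = np.asarray(A)
        B = np.asarray(B)
        if A.shape != B.shape or A.ndim != 1:
            raise ValueError(
                f"partitions must be 1-D and equal length, got {A.shape} vs {B.shape}"
            )
        _, ai_codes = np.unique(A, return_inverse=True)
        _, bj_codes = np.unique(B, return_inverse=True)
        table = np.zeros((ai_codes.max() + 1, bj_codes.max() + 1), dtype=np.int64)
        np.add.at(table, (ai_codes, bj_codes), 1)
        return cls(
            n_ij=table,
            a_i=table.sum(axis=1),
            b_j=table.sum(axis=0),
            n_total=int(A.size),
        )


def _labels_of(x):
    # accept ClusterLabels without importing the class (duck-typed)
    return x.labels if hasattr(x, "labels") else x


def adjusted_rand_index(A, B) -> float:
    """Chance-corrected agreement of two partitions.

    Accepts label sequences or ClusterLabels.  When the expected index
    equals the maximum index (the 0/0 degenerate case: both partitions a
    single cluster, or both all singletons), returns 1.0 if the partitions
    induce the same grouping and 0.0 otherwise.
    """
    A = _labels_of(A)
    B = _labels_of(B)
    ct = ContingencyTable.from_labels(A, B)
    n = ct.n_total

    sum_nij = sum(comb(int(x), 2) for x in ct.n_ij.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.a_i)
    sum_b = sum(comb(int(x), 2) for x in ct.b_j)
    total_pairs = comb(n, 2)

    if total_pairs == 0:
        return 1.0
    expected = Fraction(sum_a * sum_b, total_pairs)
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        # same grouping <=> contingency table is a (scaled) permutation matrix
        same = (
            np.count_nonzero(ct.n_ij) == ct.n_ij.shape[0] == ct.n_ij.shape[1]
        )
        return 1.0 if same else 0.0
    return float((sum_nij - expected) / (max_index - expected))


def score_ari_correlation(pairs) -> float:
    """Pearson correlation between paired (c_score, ari) observations."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (c_score, ari) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a coordinate is constant")
    return float(pearsonr(x, y).statistic)
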