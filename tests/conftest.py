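import numpy as np
import pytest

from sc3e.expr_io import ExpressionMatrix
from sc3e.sc3_core import ClusterLabels, ConsensusMatrix


def cscore_oracle(C: np.ndarray, labels: np.ndarray, alpha: float, beta: float):
    """Brute-force pair loop applying the scoring formulas verbatim.

    Independent of the graph_score implementation: no graph objects, just
    dictionaries of edge weights accumulated over every unordered pair.
    Returns (W_in, D_out, C-score).
    """
    n = len(labels)
    clusters = sorted(set(int(x) for x in labels))
    in_weights = {c: [] for c in clusters}
    out_weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            cij = C[i, j]
            if labels[i] == labels[j]:
                if cij < alpha:
                    in_weights[int(labels[i])].append(cij)
            else:
                if cij > beta:
                    key = tuple(sorted((int(labels[i]), int(labels[j]))))
                    out_weights.setdefault(key, []).append(cij)
    w = {
        c: (sum(alpha - x for x in xs) / len(xs) if xs else 0.0)
        for c, xs in in_weights.items()
    }
    d_ij = {key: sum(r - beta for r in rs) / len(rs) for key, rs in out_weights.items()}
    d = {c: sum(v for key, v in d_ij.items() if c in key) for c in clusters}
    w_in = sum(w.values()) / len(clusters)
    d_out = sum(d.values()) / len(clusters)
    return w_in, d_out, w_in * d_out


def random_consensus_instance(rng: np.random.Generator, max_n: int = 20):
    """A random valid (ConsensusMatrix, ClusterLabels) pair for oracle tests."""
    n = int(rng.integers(3, max_n + 1))
    k = int(rng.integers(2, min(n, 6) + 1))
    raw = rng.random((n, n))
    C = (raw + raw.T) / 2.0
    np.fill_diagonal(C, 1.0)
    # labels guaranteed to use every id in 1..k
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    cm = ConsensusMatrix(values=C, cell_ids=[f"c{i}" for i in range(n)])
    return cm, ClusterLabels(labels=labels, num_clusters=k)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        values=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 7.0]]),
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2"],
        units="READS",
    )
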