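"""Clustering graph, its cluster-level contraction, and the C-score.

Given a consensus matrix C and labels T:

* an in-cluster edge joins two same-cluster cells whose consensus value is
  strictly below alpha (weak within-cluster support);
* an out-cluster edge joins two different-cluster cells whose consensus
  value is strictly above beta (leakage between clusters).

Contracting each cluster to a node gives per-cluster weights

    w_i = sum(alpha - c) / k_i          (0 when the cluster has no in-edges)
    d_ij = sum(r_p - beta) / |E_ij|     (over out-edges between i and j)
    d_i = sum_{j in neighbors(i)} d_ij  (0 when isolated)

and the score W_in = mean(w_i), D_out = mean(d_i), C-score = W_in * D_out,
averaged over all cluster nodes including isolated ones.  Lower is better;
an exactly zero score is flagged because it cannot rank methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sc3e.sc3_core import ClusterLabels, ConsensusMatrix


@dataclass(frozen=True)
class GraphParams:
    """Edge thresholds: in-cluster below ``alpha``, out-cluster above ``beta``."""

    alpha: float = 0.6
    beta: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class InClusterEdge:
    cell_i: int
    cell_j: int
    weight: float
    cluster: int


@dataclass(frozen=True)
class OutClusterEdge:
    cell_i: int
    cell_j: int
    weight: float
    cluster_pair: tuple


@dataclass(frozen=True)
class ClusteringGraph:
    """Cell-level graph of weak within-cluster and leaky between-cluster pairs."""

    n_cells: int
    clusters: tuple
    in_cluster_edges: tuple
    out_cluster_edges: tuple

    def write_edges_tsv(self, path: str, cell_ids=None) -> None:
        name = (lambda i: cell_ids[i]) if cell_ids is not None else (lambda i: str(i))
        with open(path, "w") as fh:
            fh.write("cell_i\tcell_j\tweight\ttype\tcluster\n")
            for e in self.in_cluster_edges:
                fh.write(
                    f"{name(e.cell_i)}\t{name(e.cell_j)}\t{e.weight:.17g}\t"
                    f"in\t{e.cluster}\n"
                )
            for e in self.out_cluster_edges:
                a, b = e.cluster_pair
                fh.write(
                    f"{name(e.cell_i)}\t{name(e.cell_j)}\t{e.weight:.17g}\t"
                    f"out\t{a}-{b}\n"
                )


@dataclass(frozen=True)
class ContractedGraph:
    """One node per cluster with weakness w_i, leakage d_i and pair weights d_ij."""

    clusters: tuple
    w: dict  # cluster -> w_i
    d: dict  # cluster -> d_i
    k_edges: dict  # cluster -> number of in-cluster edges
    pair_weights: dict  # (cluster a, cluster b) sorted -> d_ij
    neighbors: dict = field(default_factory=dict)  # cluster -> frozenset

    def write_tsv(self, nodes_path: str, edges_path: str) -> None:
        with open(nodes_path, "w") as fh:
            fh.write("cluster\tw\td\tk_in_edges\n")
            for c in self.clusters:
                fh.write(f"{c}\t{self.w[c]:.17g}\t{self.d[c]:.17g}\t{self.k_edges[c]}\n")
        with open(edges_path, "w") as fh:
            fh.write("cluster_i\tcluster_j\td_ij\n")
            for (a, b), w in sorted(self.pair_weights.items()):
                fh.write(f"{a}\t{b}\t{w:.17g}\n")


@dataclass(frozen=True)
class CScoreResult:
    """W_in, D_out and their product; ``zero_score`` warns of an empty graph."""

    w_in: float
    d_out: float
    c_score: float
    n_clusters: int
    zero_score: bool

    def to_dict(self) -> dict:
        return {
            "w_in": self.w_in,
            "d_out": self.d_out,
            "c_score": self.c_score,
            "n_clusters": self.n_clusters,
            "zero_score": self.zero_score,
        }


def build_clustering_graph(
    C: ConsensusMatrix, T: ClusterLabels, params: GraphParams = GraphParams()
) -> ClusteringGraph:
    """Scan all unordered cell pairs and add threshold-crossing edges.

    Comparisons are strict: a consensus value exactly at alpha or beta adds
    no edge.
    """
    n = C.n_cells
    if T.n_cells != n:
        raise ValueError(f"consensus has {n} cells but labels cover {T.n_cells}")
    labels = T.labels
    vals = C.values
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    cij = vals[iu, ju]

    in_mask = same & (cij < params.alpha)
    out_mask = (~same) & (cij > params.beta)

    in_edges = tuple(
        InClusterEdge(int(i), int(j), float(c), int(labels[i]))
        for i, j, c in zip(iu[in_mask], ju[in_mask], cij[in_mask])
    )
    out_edges = tuple(
        OutClusterEdge(
            int(i),
            int(j),
            float(c),
            tuple(sorted((int(labels[i]), int(labels[j])))),
        )
        for i, j, c in zip(iu[out_mask], ju[out_mask], cij[out_mask])
    )
    clusters = tuple(sorted(set(int(x) for x in labels)))
    return ClusteringGraph(
        n_cells=n,
        clusters=clusters,
        in_cluster_edges=in_edges,
        out_cluster_edges=out_edges,
    )


def contract_graph(G: ClusteringGraph, params: GraphParams = GraphParams()) -> ContractedGraph:
    """Collapse clusters to nodes and apply the w_i / d_ij / d_i formulas."""
    w_sums = {c: 0.0 for c in G.clusters}
    k_edges = {c: 0 for c in G.clusters}
    for e in G.in_cluster_edges:
        w_sums[e.cluster] += params.alpha - e.weight
        k_edges[e.cluster] += 1
    w = {c: (w_sums[c] / k_edges[c] if k_edges[c] else 0.0) for c in G.clusters}

    pair_sums: dict = {}
    pair_counts: dict = {}
    for e in G.out_cluster_edges:
        key = e.cluster_pair
        pair_sums[key] = pair_sums.get(key, 0.0) + (e.weight - params.beta)
        pair_counts[key] = pair_counts.get(key, 0) + 1
    pair_weights = {key: pair_sums[key] / pair_counts[key] for key in pair_sums}

    neighbors = {c: set() for c in G.clusters}
    for a, b in pair_weights:
        neighbors[a].add(b)
        neighbors[b].add(a)
    d = {
        c: sum(pair_weights[tuple(sorted((c, j)))] for j in neighbors[c])
        for c in G.clusters
    }
    return ContractedGraph(
        clusters=G.clusters,
        w=w,
        d=d,
        k_edges=k_edges,
        pair_weights=pair_weights,
        neighbors={c: frozenset(v) for c, v in neighbors.items()},
    )


def c_score(CG: ContractedGraph) -> CScoreResult:
    """Average the node weights and multiply: C-score = W_in * D_out."""
    n = len(CG.clusters)
    if n == 0:
        raise ValueError("contracted graph has no cluster nodes")
    w_in = sum(CG.w[c] for c in CG.clusters) / n
    d_out = sum(CG.d[c] for c in CG.clusters) / n
    score = w_in * d_out
    return CScoreResult(
        w_in=w_in,
        d_out=d_out,
        c_score=score,
        n_clusters=n,
        zero_score=(score == 0.0),
    )


def score_clustering(
    C: ConsensusMatrix, T: ClusterLabels, params: GraphParams = GraphParams()
) -> CScoreResult:
    """Convenience: graph -> contraction -> C-score in one call."""
    return c_score(contract_graph(build_clustering_graph(C, T, params), params))
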