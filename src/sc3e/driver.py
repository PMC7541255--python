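"""End-to-end orchestration: preprocess -> consensus -> C-score -> select.

For each requested preprocessing method the consensus engine is run N times
(seeded deterministically per method and repeat), C-scores are averaged, and
the method attaining the smallest mean C-score is selected.  Ties break by
the fixed priority log > zscore > none > sctransform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from sc3e.expr_io import ExpressionMatrix
from sc3e.graph_score import CScoreResult, GraphParams, score_clustering
from sc3e.metrics import adjusted_rand_index
from sc3e.preprocess import METHODS, apply_transform
from sc3e.sc3_core import ClusterLabels, ConsensusMatrix, SC3Config, run_consensus, stable_seed

#: tie-break order for equal mean C-scores
METHOD_PRIORITY = ("log", "zscore", "none", "sctransform")


@dataclass(frozen=True)
class RepeatConfig:
    """Parameters of one SC3-e run."""

    k: int
    n_repeats: int = 1
    master_seed: int = 0
    methods: tuple = METHODS
    params: GraphParams = GraphParams()
    sc3: SC3Config = SC3Config()

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class MethodResult:
    """Per-method accumulation across repeats."""

    method: str
    scores: list = field(default_factory=list)  # CScoreResult per repeat
    consensus: ConsensusMatrix | None = None  # from the final repeat
    labels: ClusterLabels | None = None  # from the final repeat
    ari: float | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    @property
    def mean_c_score(self) -> float | None:
        if self.failed or not self.scores:
            return None
        return float(np.mean([s.c_score for s in self.scores]))


@dataclass
class SelectionReport:
    """Everything a run produced, JSON-serializable via :meth:`to_dict`."""

    config: RepeatConfig
    method_results: dict  # method -> MethodResult
    selected_method: str
    zero_score_warning: bool

    def to_dict(self) -> dict:
        methods_payload = {}
        for name, mr in self.method_results.items():
            if mr.failed:
                methods_payload[name] = {"failed": True, "error": mr.error}
                continue
            methods_payload[name] = {
                "failed": False,
                "mean_c_score": mr.mean_c_score,
                "scores": [s.to_dict() for s in mr.scores],
                "labels": mr.labels.labels.tolist(),
                "ari": mr.ari,
            }
        return {
            "k": self.config.k,
            "n_repeats": self.config.n_repeats,
            "master_seed": self.config.master_seed,
            "alpha": self.config.params.alpha,
            "beta": self.config.params.beta,
            "methods": methods_payload,
            "selected_method": self.selected_method,
            "zero_score_warning": self.zero_score_warning,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_sc3e(
    M: ExpressionMatrix,
    config: RepeatConfig,
    truth: ClusterLabels | None = None,
) -> SelectionReport:
    """Run the full selection procedure on one expression matrix.

    A method whose consensus run raises is marked failed and excluded from
    the argmin; the reported labels/consensus come from the final repeat.
    """
    if M.n_cells <= config.k:
        raise ValueError(f"need more cells than clusters (n={M.n_cells}, k={config.k})")
    results: dict = {}
    for method in config.methods:
        mr = MethodResult(method=method)
        try:
            P = apply_transform(M, method)
            for r in range(1, config.n_repeats + 1):
                seed = stable_seed(config.master_seed, method, r)
                C, T = run_consensus(P, config.k, seed, config.sc3)
                mr.scores.append(score_clustering(C, T, config.params))
                mr.consensus, mr.labels = C, T
            if truth is not None:
                mr.ari = adjusted_rand_index(truth, mr.labels)
        except Exception as exc:  # per-method isolation is the contract
            mr.error = f"{type(exc).__name__}: {exc}"
            mr.scores = []
            mr.consensus = mr.labels = None
        results[method] = mr

    selected = _argmin_method(results)
    zero_warning = any(
        s.zero_score for mr in results.values() if not mr.failed for s in mr.scores
    )
    return SelectionReport(
        config=config,
        method_results=results,
        selected_method=selected,
        zero_score_warning=zero_warning,
    )


def _argmin_method(results: dict) -> str:
    ok = {m: mr.mean_c_score for m, mr in results.items() if not mr.failed}
    if not ok:
        raise RuntimeError(
            "all methods failed: "
            + "; ".join(f"{m}: {mr.error}" for m, mr in results.items())
        )
    best = min(ok.values())
    for method in METHOD_PRIORITY:
        if method in ok and ok[method] == best:
            return method
    # methods outside the canonical priority list (cannot happen via RepeatConfig)
    return min(ok, key=lambda m: ok[m])


def select_best(report: SelectionReport) -> str:
    """The method with the smallest mean C-score (deterministic under ties)."""
    return _argmin_method(report.method_results)
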