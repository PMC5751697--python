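"""GENIE3-style network inference from pseudo-temporal expression curves.

For each target gene j, a random-forest ensemble regresses the gene's
next-time expression x_{t+1}^{(j)} on the current expression of the other
genes x_t^{(-j)} (a one-step-lagged design, so the regression respects
the arrow of pseudo-time). The forest's feature importances score each
candidate regulator; the N per-target rankings are aggregated into an
N x N weight matrix with N(N-1) candidate directed edges. Pruning is two
stage: per target keep the top-k incoming candidates, then keep edges
whose weight exceeds a threshold — in "auto" mode the threshold is
lowered along the sorted weight ladder just until every gene is incident
to at least one edge, keeping the network sparse but fully connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "Genie3Config",
    "EdgeScores",
    "PrunedNetwork",
    "Genie3Network",
    "compute_importances",
    "aggregate_edges",
    "prune_network",
]


@dataclass
class Genie3Config:
    """Random-forest settings for the per-target regressions."""

    n_trees: int = 1000
    max_features: str | int | float = "sqrt"
    seed: int = 0


@dataclass
class EdgeScores:
    """N x N candidate edge weights; weights[source, target], diagonal 0."""

    weights: np.ndarray
    gene_ids: list[str]
    config: Genie3Config = field(default_factory=Genie3Config)

    @property
    def n_candidates(self) -> int:
        """Number of defined (off-diagonal) directed candidate edges."""
        n = self.weights.shape[0]
        return n * (n - 1)


@dataclass
class PrunedNetwork:
    """Directed edge list after two-stage pruning.

    ``edges`` is a list of (source_id, target_id, weight) for the final
    network; ``stage1_edges`` the per-target top-k candidates before
    thresholding.
    """

    edges: list[tuple[str, str, float]]
    stage1_edges: list[tuple[str, str, float]]
    threshold: float
    top_per_gene: int
    gene_ids: list[str]

    def undirected_edges(self) -> list[tuple[str, str, float]]:
        """Collapse to unordered pairs: kept if either direction survives,
        weight = max of the two directions."""
        best: dict[tuple[str, str], float] = {}
        for s, t, w in self.edges:
            key = (s, t) if s <= t else (t, s)
            best[key] = max(best.get(key, -np.inf), w)
        return [(s, t, w) for (s, t), w in sorted(best.items())]

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        g.add_weighted_edges_from(self.edges)
        return g


def _lagged_design(values: np.ndarray, target: int) -> tuple[np.ndarray, np.ndarray]:
    """One-step-lagged design: X = other genes at t, y = target at t+1."""
    regulators = [g for g in range(values.shape[0]) if g != target]
    X = values[regulators, :-1].T
    y = values[target, 1:]
    return X, y


def compute_importances(
    values: np.ndarray, target_gene: int, cfg: Genie3Config | None = None
) -> np.ndarray:
    """Per-regulator importance for one target gene (length N-1).

    ``values`` is a genes x timepoints matrix (smoothed curves or raw
    ordered expression). Importances are normalized to sum to 1 when any
    is positive; a constant target yields an all-zero vector.
    """
    cfg = cfg or Genie3Config()
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    X, y = _lagged_design(values, target_gene)
    if np.ptp(y) == 0:
        return np.zeros(n_genes - 1)
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    imp = rf.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp


def aggregate_edges(
    importances: list[np.ndarray],
    gene_ids: list[str] | None = None,
    config: Genie3Config | None = None,
) -> EdgeScores:
    """Assemble per-target importance vectors into the N x N weight matrix.

    ``importances[j]`` scores the N-1 regulators of target j (in gene
    order with gene j skipped); weights[source, target] holds the score.
    The candidate count is N(N-1).
    """
    n = len(importances)
    weights = np.zeros((n, n))
    for j, imp in enumerate(importances):
        imp = np.asarray(imp, dtype=float)
        if imp.shape != (n - 1,):
            raise ValueError(
                f"importance vector for target {j} has shape {imp.shape}, "
                f"expected ({n - 1},)"
            )
        regulators = [g for g in range(n) if g != j]
        weights[regulators, j] = imp
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    return EdgeScores(weights=weights, gene_ids=list(gene_ids),
                      config=config or Genie3Config())


def _incident_cover(edges: list[tuple[int, int, float]], n: int, threshold: float) -> bool:
    incident = np.zeros(n, dtype=bool)
    for s, t, w in edges:
        if w > threshold:
            incident[s] = incident[t] = True
    return bool(incident.all())


def auto_threshold(edges: list[tuple[int, int, float]], n: int) -> float:
    """Largest threshold such that {edges with weight > threshold} touches
    every gene; scans the sorted ladder of candidate weights (plus 0)."""
    candidates = sorted({w for _, _, w in edges} | {0.0}, reverse=True)
    for thr in candidates:
        if _incident_cover(edges, n, thr):
            return thr
    raise ValueError("cannot connect all genes even at threshold 0")


def prune_network(
    scores: EdgeScores,
    top_per_gene: int = 10,
    threshold: float | str = "auto",
) -> PrunedNetwork:
    """Two-stage pruning of the candidate edge matrix.

    Stage 1 keeps, for each target gene, its ``top_per_gene``
    highest-weight incoming candidates (ties broken by source index).
    Stage 2 keeps stage-1 edges with weight strictly above ``threshold``;
    "auto" lowers the threshold down the sorted weight ladder until every
    gene is incident to at least one retained edge, then stops.
    """
    if top_per_gene < 1:
        raise ValueError("top_per_gene must be >= 1")
    w = scores.weights
    n = w.shape[0]
    stage1: list[tuple[int, int, float]] = []
    for t in range(n):
        sources = [s for s in range(n) if s != t]
        ranked = sorted(sources, key=lambda s: (-w[s, t], s))
        for s in ranked[:top_per_gene]:
            stage1.append((s, t, float(w[s, t])))
    if threshold == "auto":
        thr = auto_threshold(stage1, n)
        final = [e for e in stage1 if e[2] > thr]
    else:
        thr = float(threshold)
        # thr == 0 is a documented stage-2 no-op; a strict inequality
        # would silently drop exact-zero weights that stage 1 retained
        final = list(stage1) if thr == 0 else [e for e in stage1 if e[2] > thr]
    ids = scores.gene_ids
    return PrunedNetwork(
        edges=[(ids[s], ids[t], wt) for s, t, wt in final],
        stage1_edges=[(ids[s], ids[t], wt) for s, t, wt in stage1],
        threshold=thr,
        top_per_gene=top_per_gene,
        gene_ids=list(ids),
    )


class Genie3Network(BaseEstimator):
    """GENIE3-style network inference estimator.

    Fit on a genes x timepoints matrix (rows in gene order, columns in
    pseudo-time order). Fitted attributes:

    importances_ : N x N weight matrix (source, target)
    scores_ : EdgeScores
    network_ : PrunedNetwork
    """

    def __init__(
        self,
        n_trees: int = 1000,
        max_features: str | int | float = "sqrt",
        top_per_gene: int = 10,
        threshold: float | str = "auto",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.top_per_gene = top_per_gene
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, gene_ids: list[str] | None = None
            ) -> "Genie3Network":
        X = np.asarray(X, dtype=float)
        cfg = Genie3Config(
            n_trees=self.n_trees,
            max_features=self.max_features,
            seed=self.random_state,
        )
        imps = [compute_importances(X, j, cfg) for j in range(X.shape[0])]
        self.scores_ = aggregate_edges(imps, gene_ids=gene_ids, config=cfg)
        self.importances_ = self.scores_.weights
        self.network_ = prune_network(
            self.scores_, top_per_gene=self.top_per_gene, threshold=self.threshold
        )
        return self
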