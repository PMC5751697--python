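"""Wanderlust-style pseudo-temporal ordering on l-out-of-k nearest-neighbour graphs.

Cells (usually already embedded in diffusion coordinates) are connected
into a k-nearest-neighbour graph from which ``l`` neighbours per cell are
randomly subsampled (an l-k-NNG); randomization over several graph
realizations averages out spurious short-circuit edges. A start cell and
a set of randomly chosen landmark cells anchor the trajectory: each cell
receives a score built from graph shortest-path distances to the
landmarks,

    Score_t = sum_l sign_l(t) * (d(l, t) / n_l) * w_{l,t},
    w_{l,t} = d(l, t)^2 / sum_m d(l, m)^2   (m over landmarks),

where sign_l(t) is negative when cell t precedes landmark l (initially:
d(s, t) < d(s, l) relative to the start cell s, then relative to the
previous iteration's scores). The scoring/orientation step is repeated
until landmark scores converge. Sorting cells by the final averaged score
yields the pseudo-trajectory; ordered cell r is assigned pseudo-time r
(one cell = one unit time), so N cells span [0, N-1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LknnGraph",
    "PseudoTrajectory",
    "WanderlustOrdering",
    "build_lknn_graph",
    "landmark_weight",
    "trajectory_scores",
    "order_cells",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LknnGraph:
    """Sparse directed l-out-of-k NN graph with Euclidean edge lengths.

    ``adjacency[i, j]`` holds the Euclidean length of the edge i -> j for
    the l neighbours retained for cell i. Shortest paths treat edges as
    traversable in both directions.
    """

    adjacency: csr_matrix
    k: int
    l: int
    seed: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        row = self.adjacency.getrow(i)
        return list(zip(row.indices.tolist(), row.data.tolist()))

    def shortest_paths(self, sources: Sequence[int]) -> np.ndarray:
        """Dijkstra distances from each source to every cell (undirected)."""
        return dijkstra(self.adjacency, directed=False, indices=list(sources))


@dataclass
class PseudoTrajectory:
    """A pseudo-temporal ordering of cells.

    ``order[r]`` is the index of the cell at rank r (ascending score);
    ``pseudotime[i]`` = rank of cell i, on the unit-time convention
    (N cells span pseudo-times 0 .. N-1).
    """

    order: np.ndarray
    scores: np.ndarray
    start_cell: int
    landmarks: np.ndarray
    n_iterations: int
    converged: bool = True

    @property
    def pseudotime(self) -> np.ndarray:
        t = np.empty(len(self.order), dtype=int)
        t[self.order] = np.arange(len(self.order))
        return t

    @property
    def horizon(self) -> int:
        """Final pseudo-time point: N - 1."""
        return len(self.order) - 1


def build_lknn_graph(points: np.ndarray, k: int, l: int, seed: int = 0) -> LknnGraph:
    """Build an l-out-of-k nearest-neighbour graph (Euclidean metric).

    Each cell is connected to its k nearest neighbours, of which l are
    kept, drawn uniformly without replacement with the given seed
    (``l == k`` keeps all of them, deterministically).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if not 1 <= l <= k:
        raise ValueError(f"need 1 <= l <= k, got l={l}, k={k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self-neighbour
    rng = np.random.default_rng(seed)
    rows, cols, data = [], [], []
    for i in range(n):
        pick = np.arange(k) if l == k else rng.choice(k, size=l, replace=False)
        rows.extend([i] * l)
        cols.extend(idx[i, pick].tolist())
        data.extend(dist[i, pick].tolist())
    adjacency = csr_matrix((data, (rows, cols)), shape=(n, n))
    return LknnGraph(adjacency=adjacency, k=k, l=l, seed=seed)


def _landmark_weights(landmarks: Sequence[int], dist: np.ndarray) -> np.ndarray:
    """Weight matrix w[li, t] = d(l, t)^2 / sum_m d(l, m)^2, m over landmarks.

    ``dist`` is (n_landmarks, N), row order matching ``landmarks``. If a
    landmark is equidistant-zero from every other landmark (single
    landmark at the start, say) the normalizer vanishes and the weights
    fall back to 1, leaving the plain distance score.
    """
    if not np.isfinite(dist).all():
        bad = int(np.argwhere(~np.isfinite(dist))[0, 1])
        raise ValueError(f"graph disconnected: cell {bad} unreachable from a landmark")
    d2 = dist**2
    denom = d2[:, list(landmarks)].sum(axis=1)
    w = np.ones_like(d2)
    ok = denom > 0
    w[ok] = d2[ok] / denom[ok, None]
    return w


def landmark_weight(
    l_cell: int, t_cell: int, landmarks: Sequence[int], dist: np.ndarray
) -> float:
    """Weight of landmark ``l_cell`` for cell ``t_cell``.

    ``dist`` is the (n_landmarks, N) matrix of graph shortest-path
    distances from each landmark (row order = ``landmarks``).
    """
    landmarks = list(landmarks)
    li = landmarks.index(l_cell)
    return float(_landmark_weights(landmarks, dist)[li, t_cell])


def _score_pass(
    dist_landmarks: np.ndarray,
    landmarks: Sequence[int],
    ref_scores: np.ndarray,
) -> np.ndarray:
    """One orientation + scoring pass given reference scores."""
    n_l = len(landmarks)
    w = _landmark_weights(landmarks, dist_landmarks)
    signs = np.where(
        ref_scores[None, :] < ref_scores[list(landmarks), None], -1.0, 1.0
    )
    return (signs * dist_landmarks * w).sum(axis=0) / n_l


def trajectory_scores(
    graph: LknnGraph,
    start: int,
    landmarks: Sequence[int],
    max_iter: int = 50,
    tol: float = 1e-3,
) -> tuple[np.ndarray, int, bool]:
    """Iterated landmark trajectory scores on one graph realization.

    Initial scores are shortest-path distances from the start cell; each
    pass re-orients every landmark contribution by the previous scores
    and re-scores, until the maximum change in (range-normalized)
    landmark scores drops below ``tol`` or ``max_iter`` passes are spent.

    Returns ``(scores, n_iterations, converged)``.
    """
    landmarks = list(landmarks)
    dist_start = graph.shortest_paths([start])[0]
    if not np.isfinite(dist_start).all():
        bad = int(np.argwhere(~np.isfinite(dist_start))[0, 0])
        raise ValueError(f"graph disconnected: cell {bad} unreachable from start")
    dist_landmarks = graph.shortest_paths(landmarks)
    scores = dist_start.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_scores = _score_pass(dist_landmarks, landmarks, scores)
        old_n = _normalize(scores)[landmarks]
        new_n = _normalize(new_scores)[landmarks]
        scores = new_scores
        if np.max(np.abs(new_n - old_n)) < tol:
            converged = True
            break
    return scores, it, converged


def _normalize(scores: np.ndarray) -> np.ndarray:
    rng = scores.max() - scores.min()
    if rng == 0:
        return np.zeros_like(scores)
    return (scores - scores.min()) / rng


def order_cells(
    emb: np.ndarray,
    start: int | str = "auto",
    k: int = 30,
    l: int = 15,
    n_landmarks: int = 20,
    n_graphs: int = 5,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 50,
    graph_seeds: Sequence[int] | None = None,
) -> PseudoTrajectory:
    """Order cells along a non-branching trajectory.

    Scores are averaged over ``n_graphs`` seeded l-k-NNG realizations
    (landmarks are drawn once and shared). ``start="auto"`` picks the
    extremum of the first embedding coordinate. The final ordering sorts
    the averaged scores ascending with ties broken by cell index.
    """
    emb = np.asarray(emb, dtype=float)
    if emb.ndim == 1:
        emb = emb[:, None]
    n = emb.shape[0]
    if start == "auto":
        start = int(np.argmax(np.abs(emb[:, 0])))
    start = int(start)
    rng = np.random.default_rng(seed)
    n_landmarks = min(n_landmarks, n - 1)
    candidates = np.setdiff1d(np.arange(n), [start])
    landmarks = np.sort(rng.choice(candidates, size=n_landmarks, replace=False))
    if graph_seeds is None:
        graph_seeds = [int(seed) + 1 + g for g in range(n_graphs)]
    all_scores = []
    n_iter_max, all_converged = 0, True
    for gseed in graph_seeds:
        graph = build_lknn_graph(emb, k=min(k, n - 1), l=min(l, min(k, n - 1)), seed=gseed)
        scores, its, conv = trajectory_scores(
            graph, start, landmarks, max_iter=max_iter, tol=tol
        )
        all_scores.append(scores)
        n_iter_max = max(n_iter_max, its)
        all_converged &= conv
    if not all_converged:
        warnings.warn(
            "landmark scores did not converge within the iteration cap; "
            "returning the best iterate",
            ConvergenceWarning,
        )
    mean_scores = np.mean(all_scores, axis=0)
    order = np.lexsort((np.arange(n), mean_scores))
    return PseudoTrajectory(
        order=order,
        scores=mean_scores,
        start_cell=start,
        landmarks=landmarks,
        n_iterations=n_iter_max,
        converged=all_converged,
    )


class WanderlustOrdering(BaseEstimator):
    """Pseudo-temporal ordering estimator (non-branching trajectory).

    Fit on an (n_cells, d) embedding; exposes the ordering as fitted
    attributes. ``fit_transform`` returns per-cell pseudo-times on the
    unit-time grid.

    Parameters mirror :func:`order_cells`; ``random_state`` seeds both
    landmark choice and the graph subsampling.
    """

    def __init__(
        self,
        start_cell: int | str = "auto",
        k: int = 30,
        l: int = 15,
        n_landmarks: int = 20,
        n_graphs: int = 5,
        tol: float = 1e-3,
        max_iter: int = 50,
        random_state: int = 0,
    ):
        self.start_cell = start_cell
        self.k = k
        self.l = l
        self.n_landmarks = n_landmarks
        self.n_graphs = n_graphs
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "WanderlustOrdering":
        traj = order_cells(
            X,
            start=self.start_cell,
            k=self.k,
            l=self.l,
            n_landmarks=self.n_landmarks,
            n_graphs=self.n_graphs,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.trajectory_ = traj
        self.order_ = traj.order
        self.scores_ = traj.scores
        self.pseudotime_ = traj.pseudotime
        self.start_cell_ = traj.start_cell
        self.landmarks_ = traj.landmarks
        self.n_iterations_ = traj.n_iterations
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).pseudotime_
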