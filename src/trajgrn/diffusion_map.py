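"""Diffusion-map embedding of single cells.

Cells are treated as points in gene-expression space. A Gaussian kernel

    W_ij = exp(-||x_i - x_j||^2 / (2 eps))

is row-normalized into a Markov matrix M whose spectrum organises the
cells by their underlying geometry: the trivial eigenpair (eigenvalue 1,
constant eigenvector) is discarded and the next ``d`` right-eigenvectors,
ordered by descending eigenvalue, are the diffusion coordinates. On data
lying along a one-dimensional developmental progression the first
non-trivial coordinate is monotone in the latent parameter, which is what
makes the embedding a suitable substrate for trajectory detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "KernelMatrix",
    "MarkovMatrix",
    "DiffusionEmbedding",
    "DiffusionMap",
    "gaussian_kernel",
    "markov_normalize",
    "embed",
    "median_bandwidth",
]


@dataclass
class KernelMatrix:
    """Symmetric Gaussian affinity matrix with unit diagonal."""

    W: np.ndarray
    epsilon: float


@dataclass
class MarkovMatrix:
    """Row-stochastic transition matrix M = W / P with row sums P."""

    M: np.ndarray
    P: np.ndarray


@dataclass
class DiffusionEmbedding:
    """Non-trivial diffusion coordinates and their eigenvalues (descending)."""

    coords: np.ndarray
    eigenvalues: np.ndarray


def median_bandwidth(points: np.ndarray) -> float:
    """Median of squared pairwise Euclidean distances (default kernel scale)."""
    d2 = pdist(np.asarray(points, dtype=float), metric="sqeuclidean")
    eps = float(np.median(d2))
    if eps <= 0:
        raise ValueError("degenerate data: median pairwise distance is zero")
    return eps


def gaussian_kernel(points: np.ndarray, epsilon: float) -> KernelMatrix:
    """Isotropic Gaussian kernel W_ij = exp(-||x_i - x_j||^2 / (2 epsilon)).

    ``points`` is an (N, D) array of cells as rows; ``epsilon`` is the
    bandwidth controlling the neighbourhood size.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least two cells")
    d2 = squareform(pdist(points, metric="sqeuclidean"))
    W = np.exp(-d2 / (2.0 * epsilon))
    np.fill_diagonal(W, 1.0)
    return KernelMatrix(W=W, epsilon=float(epsilon))


def markov_normalize(kernel: KernelMatrix) -> MarkovMatrix:
    """Row-normalize the kernel: M_ij = W_ij / P(x_i), P(x_i) = sum_j W_ij."""
    W = kernel.W
    P = W.sum(axis=1)
    if np.any(P <= 0):
        raise FloatingPointError("zero row sum in kernel matrix")
    return MarkovMatrix(M=W / P[:, None], P=P)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def embed(markov: MarkovMatrix, d: int) -> DiffusionEmbedding:
    """Spectral embedding from the Markov matrix.

    M = D^{-1} W is conjugate to the symmetric S = D^{-1/2} W D^{-1/2},
    so its eigenvalues are real and its right-eigenvectors are
    D^{-1/2} (eigenvectors of S). The leading eigenpair (eigenvalue 1,
    constant direction) carries no geometry and is dropped; the next
    ``d`` eigenvectors, by descending eigenvalue, are returned with a
    deterministic sign convention.
    """
    M, P = markov.M, markov.P
    N = M.shape[0]
    if not 1 <= d <= N - 1:
        raise ValueError(f"d must be in [1, {N - 1}], got {d}")
    W = M * P[:, None]
    inv_sqrt = 1.0 / np.sqrt(P)
    S = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    S = (S + S.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # right-eigenvectors of M, skipping the trivial leading pair
    psi = inv_sqrt[:, None] * eigvecs[:, 1 : d + 1]
    psi = _fix_signs(psi)
    return DiffusionEmbedding(coords=psi, eigenvalues=eigvals[1 : d + 1])


class DiffusionMap(BaseEstimator, TransformerMixin):
    """Diffusion-map embedding estimator.

    Parameters
    ----------
    n_components : int, default=3
        Number of non-trivial diffusion coordinates to keep.
    epsilon : "median" or float, default="median"
        Kernel bandwidth; "median" uses the median squared pairwise
        distance of the fitted data.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_cells, n_components)
    eigenvalues_ : ndarray of shape (n_components,)
    epsilon_ : float
        The bandwidth actually used.
    """

    def __init__(self, n_components: int = 3, epsilon: float | str = "median"):
        self.n_components = n_components
        self.epsilon = epsilon

    def fit(self, X: np.ndarray, y=None) -> "DiffusionMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (cells x features) array")
        eps = median_bandwidth(X) if self.epsilon == "median" else float(self.epsilon)
        kernel = gaussian_kernel(X, eps)
        markov = markov_normalize(kernel)
        emb = embed(markov, self.n_components)
        self.epsilon_ = eps
        self.embedding_ = emb.coords
        self.eigenvalues_ = emb.eigenvalues
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).embedding_

    def transform(self, X: np.ndarray) -> np.ndarray:
        # The embedding is defined only on the fitted cells.
        raise NotImplementedError(
            "DiffusionMap embeds the fitted cells; use fit_transform"
        )
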