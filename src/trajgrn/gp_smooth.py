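"""Gaussian-process smoothing of pseudo-trajectory expression profiles.

Expression along the pseudo-trajectory is noisy cell-to-cell; each gene's
profile is modelled as y = f(t) + eps, eps ~ N(0, sigma_n^2 I), with a GP
prior on f under the squared-exponential covariance

    K(t, t') = sigma^2 exp(-(t - t')^2 / (2 l^2)).

The posterior at test points t* is Gaussian with

    mu    = K_* (K + sigma_n^2 I)^{-1} y
    Sigma = K_** - K_* (K + sigma_n^2 I)^{-1} K_*^T,

computed here with a Cholesky solve. Hyperparameters are either fixed or
fitted per gene by maximizing the log marginal likelihood over
log-parameters. For long trajectories the training set can be evenly
subsampled (the cubic-cost solve is in the training size only; the
posterior is still evaluated on the full unit-time grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GpHyperparams",
    "SmoothedCurves",
    "GPSmoother",
    "se_kernel",
    "gp_posterior",
    "smooth_all_genes",
]

JITTER = 1e-8


@dataclass
class GpHyperparams:
    """Squared-exponential kernel hyperparameters.

    sigma2 : signal variance (expression units squared)
    length_scale : correlation length along pseudo-time (unit times)
    noise_var : observation noise variance
    """

    sigma2: float
    length_scale: float
    noise_var: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.length_scale <= 0:
            raise ValueError("sigma2 and length_scale must be positive")
        if self.noise_var < 0:
            raise ValueError("noise_var must be nonnegative")


@dataclass
class SmoothedCurves:
    """Per-gene posterior mean and variance over the pseudo-time grid."""

    grid: np.ndarray
    mean: np.ndarray  # (n_genes, n_grid)
    variance: np.ndarray  # (n_genes, n_grid)
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


def se_kernel(t: float | np.ndarray, t_prime: float | np.ndarray, hp: GpHyperparams):
    """Squared-exponential covariance K = sigma^2 exp(-(t-t')^2 / (2 l^2))."""
    diff = np.asarray(t, dtype=float) - np.asarray(t_prime, dtype=float)
    return hp.sigma2 * np.exp(-(diff**2) / (2.0 * hp.length_scale**2))


def _kernel_matrix(t1: np.ndarray, t2: np.ndarray, hp: GpHyperparams) -> np.ndarray:
    return se_kernel(t1[:, None], t2[None, :], hp)


def gp_posterior(
    t_train: np.ndarray,
    y_train: np.ndarray,
    t_test: np.ndarray,
    hp: GpHyperparams,
    jitter: float = JITTER,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and pointwise variance at ``t_test``.

    Solves (K + sigma_n^2 I) alpha = y by Cholesky; a small jitter keeps
    the factorization stable in the noise-free limit.
    """
    t_train = np.asarray(t_train, dtype=float).ravel()
    y_train = np.asarray(y_train, dtype=float).ravel()
    t_test = np.asarray(t_test, dtype=float).ravel()
    if t_train.size == 0:
        raise ValueError("t_train must be nonempty")
    K = _kernel_matrix(t_train, t_train, hp)
    K[np.diag_indices_from(K)] += hp.noise_var + jitter
    try:
        cf = cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError("kernel matrix not positive definite") from exc
    Ks = _kernel_matrix(t_test, t_train, hp)
    alpha = cho_solve(cf, y_train)
    mean = Ks @ alpha
    v = cho_solve(cf, Ks.T)
    var = hp.sigma2 - np.einsum("ij,ji->i", Ks, v)
    return mean, np.maximum(var, 0.0)


def _neg_log_marginal_likelihood(
    log_params: np.ndarray, t: np.ndarray, y: np.ndarray, jitter: float
) -> float:
    sigma2, length_scale, noise_var = np.exp(log_params)
    hp = GpHyperparams(sigma2, length_scale, noise_var)
    K = _kernel_matrix(t, t, hp)
    K[np.diag_indices_from(K)] += noise_var + jitter
    try:
        cf = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25
    alpha = cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(0.5 * y @ alpha + 0.5 * logdet + 0.5 * len(y) * np.log(2 * np.pi))


def fit_hyperparams(
    t: np.ndarray, y: np.ndarray, jitter: float = JITTER
) -> GpHyperparams:
    """Maximize the log marginal likelihood over (sigma2, l, noise_var)."""
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    var_y = float(np.var(y))
    if var_y == 0:
        # flat profile: any length scale works, keep the prior tight
        span = max(float(np.ptp(t)), 1.0)
        return GpHyperparams(1e-6, span / 5.0, 1e-6)
    span = max(float(np.ptp(t)), 1.0)
    x0 = np.log([var_y, span / 10.0, 0.1 * var_y])
    res = minimize(
        _neg_log_marginal_likelihood,
        x0,
        args=(t, y, jitter),
        method="L-BFGS-B",
        bounds=[(-20, 20), (np.log(span / 1000.0), np.log(10 * span)), (-20, 20)],
    )
    sigma2, length_scale, noise_var = np.exp(res.x)
    return GpHyperparams(float(sigma2), float(length_scale), float(noise_var))


class GPSmoother(BaseEstimator, RegressorMixin):
    """GP regression smoother for a single expression profile.

    Parameters
    ----------
    hp_mode : {"fit", "fixed"}, default="fit"
        "fit" maximizes the marginal likelihood per profile; "fixed" uses
        the supplied hyperparameters.
    sigma2, length_scale, noise_var : float
        Hyperparameters used in "fixed" mode (and ignored in "fit" mode).
    subsample : int or None
        Keep every ``subsample``-th training point (None = all).

    Attributes
    ----------
    hp_ : GpHyperparams actually used.
    t_train_, y_train_ : the (possibly subsampled) training data.
    """

    def __init__(
        self,
        hp_mode: str = "fit",
        sigma2: float = 1.0,
        length_scale: float = 1.0,
        noise_var: float = 0.1,
        subsample: int | None = None,
        jitter: float = JITTER,
    ):
        self.hp_mode = hp_mode
        self.sigma2 = sigma2
        self.length_scale = length_scale
        self.noise_var = noise_var
        self.subsample = subsample
        self.jitter = jitter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPSmoother":
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.subsample is not None and self.subsample > 1:
            t, y = t[:: self.subsample], y[:: self.subsample]
        # centre the targets: the GP prior has zero mean, so an uncentred
        # profile would be shrunk toward zero away from the data
        self.y_mean_ = float(np.mean(y))
        if self.hp_mode == "fit":
            self.hp_ = fit_hyperparams(t, y - self.y_mean_, jitter=self.jitter)
        elif self.hp_mode == "fixed":
            self.hp_ = GpHyperparams(self.sigma2, self.length_scale, self.noise_var)
        else:
            raise ValueError(f"unknown hp_mode {self.hp_mode!r}")
        self.t_train_, self.y_train_ = t, y
        return self

    def predict(self, X: np.ndarray, return_var: bool = False):
        t_test = np.asarray(X, dtype=float).ravel()
        mean, var = gp_posterior(
            self.t_train_, self.y_train_ - self.y_mean_, t_test, self.hp_,
            jitter=self.jitter,
        )
        mean = mean + self.y_mean_
        return (mean, var) if return_var else mean


def smooth_all_genes(
    trajectory,
    matrix,
    hp_mode: str = "fit",
    subsample: int | None = 4,
    hp: GpHyperparams | None = None,
    jitter: float = JITTER,
) -> SmoothedCurves:
    """Smooth every gene of a shifted matrix along a pseudo-trajectory.

    Columns of ``matrix`` are reordered by ``trajectory.order``, each
    gene is fitted on (pseudo-time, expression) — optionally on an evenly
    subsampled training set — and the posterior is evaluated on the full
    unit-time grid 0 .. N-1.
    """
    order = np.asarray(trajectory.order)
    values = matrix.values[:, order]
    n_genes, n_cells = values.shape
    grid = np.arange(n_cells, dtype=float)
    mean = np.empty((n_genes, n_cells))
    variance = np.empty((n_genes, n_cells))
    for g in range(n_genes):
        smoother = GPSmoother(
            hp_mode=hp_mode,
            sigma2=hp.sigma2 if hp else 1.0,
            length_scale=hp.length_scale if hp else 1.0,
            noise_var=hp.noise_var if hp else 0.1,
            subsample=subsample,
            jitter=jitter,
        )
        try:
            smoother.fit(grid, values[g])
            mean[g], variance[g] = smoother.predict(grid, return_var=True)
        except Exception as exc:
            raise RuntimeError(
                f"GP smoothing failed for gene {matrix.gene_ids[g]!r}: {exc}"
            ) from exc
    return SmoothedCurves(
        grid=grid, mean=mean, variance=variance, gene_ids=list(matrix.gene_ids)
    )
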