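"""ABC rejection sampling of ODE model parameters against smoothed trajectories.

Candidate parameter vectors are drawn from independent uniform priors,
the model is simulated piecewise (restarting every ``segment_len`` unit
times from the observed data), and each draw is scored by the relative
absolute error

    E = sum_i sum_j |x_ij - x*_ij| / max_j{x*_ij},

normalizing each gene by its maximum observed value, together with the
segment transfer probability

    L(theta) = f_0 * prod_i (1 / E_i),    f_0 = 1,

the product of reciprocal per-segment errors (a trailing short segment
counts as its own factor). Draws are ranked by ascending total error and
the top ``top_n`` (default 5) are marked accepted; a secondary
robustness criterion can then discriminate among them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .dynamic_model import OdeModelSpec, SimulatedTrajectory, simulate_piecewise
from .gp_smooth import SmoothedCurves

__all__ = [
    "PriorSpec",
    "AbcResult",
    "AbcOdeFitter",
    "simulation_error",
    "transfer_probability",
    "abc_rejection",
]

#: default prior boxes per parameter family (broad positive ranges)
DEFAULT_FAMILY_BOUNDS: dict[str, tuple[float, float]] = {
    "c": (0.0, 5.0),
    "k0": (1e-6, 5.0),
    "d0": (1e-6, 5.0),
    "A": (1.0, 10.0),
    "a": (0.0, 5.0),
    "b": (0.0, 5.0),
}


@dataclass
class PriorSpec:
    """Independent uniform prior bounds, one entry per free parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lower < upper")

    @property
    def names(self) -> list[str]:
        return list(self.bounds.keys())

    @classmethod
    def from_families(
        cls,
        spec: OdeModelSpec,
        family_bounds: Mapping[str, tuple[float, float]] | None = None,
        only: Sequence[str] | None = None,
    ) -> "PriorSpec":
        """One prior per free parameter of ``spec``, bounds per family.

        ``only`` restricts the free set to the named parameters (the rest
        stay fixed at the template's values).
        """
        fb = dict(DEFAULT_FAMILY_BOUNDS)
        if family_bounds:
            fb.update(family_bounds)
        names = spec.free_parameter_names() if only is None else list(only)
        return cls({n: fb[n.split("[")[0]] for n in names})

    @classmethod
    def around(
        cls, spec: OdeModelSpec, names: Sequence[str], rel_width: float
    ) -> "PriorSpec":
        """Multiplicative box [(1-w) theta, (1+w) theta] around the
        template's values (a "tight prior" for recovery experiments)."""
        return cls({
            n: (spec.get_parameter(n) * (1 - rel_width),
                spec.get_parameter(n) * (1 + rel_width))
            for n in names
        })

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            n: float(rng.uniform(lo, hi)) for n, (lo, hi) in self.bounds.items()
        }


@dataclass
class AbcResult:
    """Ranked ABC draws.

    ``order`` ranks draw indices by ascending total error; the first
    ``top_n`` are the accepted sets. ``exact_fit[i]`` flags a draw with a
    zero-error segment (its transfer probability is +inf).
    """

    thetas: list[dict[str, float]]
    errors: np.ndarray
    transfer_probs: np.ndarray
    segment_errors: list[list[float]]
    order: np.ndarray
    top_n: int
    seed: int
    n_failed: int = 0
    exact_fit: np.ndarray | None = None
    specs: list[OdeModelSpec] = field(default_factory=list)

    @property
    def accepted(self) -> np.ndarray:
        return self.order[: self.top_n]

    @property
    def best_theta(self) -> dict[str, float]:
        return self.thetas[int(self.order[0])]

    @property
    def best_spec(self) -> OdeModelSpec:
        return self.specs[int(self.order[0])]


def simulation_error(sim, obs: SmoothedCurves | np.ndarray) -> float:
    """Relative absolute error between simulation and observation.

    E = sum_i sum_j |x_ij - x*_ij| / max_j{x*_ij}, each gene normalized
    by its maximum observed value. NaNs in the simulation (failed
    segments) make the error infinite.
    """
    sim_states = sim.states if isinstance(sim, SimulatedTrajectory) else np.asarray(sim, float)
    obs_states = obs.mean if isinstance(obs, SmoothedCurves) else np.asarray(obs, float)
    if sim_states.shape != obs_states.shape:
        raise ValueError(
            f"shape mismatch: sim {sim_states.shape} vs obs {obs_states.shape}"
        )
    gene_max = obs_states.max(axis=1)
    if np.any(gene_max == 0):
        bad = int(np.argwhere(gene_max == 0)[0, 0])
        raise ValueError(f"gene {bad} has zero maximum observed value; "
                         "normalization undefined")
    if np.any(np.isnan(sim_states)):
        return math.inf
    return float((np.abs(sim_states - obs_states) / gene_max[:, None]).sum())


def transfer_probability(segment_errors: Sequence[float]) -> float:
    """L(theta) = product of reciprocal per-segment errors (f_0 = 1).

    A zero segment error (exact fit) yields +inf.
    """
    L = 1.0
    for e in segment_errors:
        if e < 0:
            raise ValueError("segment errors must be nonnegative")
        if e == 0:
            return math.inf
        L /= e
    return L


def _segment_errors(
    sim: SimulatedTrajectory, obs: SmoothedCurves
) -> list[float]:
    """Per-segment relative absolute errors (same normalizer as the total)."""
    obs_states = np.asarray(obs.mean)
    gene_max = obs_states.max(axis=1)
    errors = []
    failed = {(t0, t1) for t0, t1, _ in sim.failures}
    for t0, t1 in sim.segment_bounds:
        j0, j1 = int(t0), int(t1)
        j1 = j1 + 1 if t1 == sim.times[-1] else j1
        if (t0, t1) in failed:
            errors.append(math.inf)
            continue
        piece = sim.states[:, j0:j1]
        ref = obs_states[:, j0:j1]
        errors.append(float((np.abs(piece - ref) / gene_max[:, None]).sum()))
    return errors


def abc_rejection(
    template: OdeModelSpec,
    priors: PriorSpec,
    obs: SmoothedCurves,
    n_samples: int = 1000,
    seed: int = 0,
    top_n: int = 5,
    segment_len: int = 100,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> AbcResult:
    """Uniform-prior rejection sampling ranked by simulation error.

    Draws ``n_samples`` parameter vectors, simulates each piecewise
    against ``obs``, computes the total error E and the transfer
    probability L, and ranks by ascending E (failed simulations get
    infinite E and never abort the run). The top ``top_n`` draws are the
    accepted sets.
    """
    if not n_samples >= top_n >= 1:
        raise ValueError("need n_samples >= top_n >= 1")
    rng = np.random.default_rng(seed)
    thetas, specs = [], []
    errors = np.empty(n_samples)
    tprobs = np.empty(n_samples)
    seg_errors: list[list[float]] = []
    exact = np.zeros(n_samples, dtype=bool)
    n_failed = 0
    for i in range(n_samples):
        theta = priors.sample(rng)
        thetas.append(theta)
        spec = template.with_parameters(theta)
        specs.append(spec)
        try:
            sim = simulate_piecewise(spec, obs, segment_len=segment_len,
                                     rtol=rtol, atol=atol)
            errs = _segment_errors(sim, obs)
            errors[i] = simulation_error(sim, obs)
        except Exception:
            errs = [math.inf]
            errors[i] = math.inf
        if not math.isfinite(errors[i]):
            n_failed += 1
        seg_errors.append(errs)
        tprobs[i] = transfer_probability(errs)
        exact[i] = any(e == 0 for e in errs)
    if n_failed == n_samples:
        raise RuntimeError(
            f"all {n_samples} draws failed to simulate; "
            "check the template spec and prior ranges"
        )
    order = np.lexsort((np.arange(n_samples), errors))
    return AbcResult(
        thetas=thetas, errors=errors, transfer_probs=tprobs,
        segment_errors=seg_errors, order=order, top_n=top_n, seed=seed,
        n_failed=n_failed, exact_fit=exact, specs=specs,
    )


class AbcOdeFitter(BaseEstimator):
    """scikit-learn-style wrapper around :func:`abc_rejection`.

    ``fit(obs)`` runs the sampler against a
    :class:`~trajgrn.gp_smooth.SmoothedCurves` observation and exposes
    ``result_``, ``best_spec_`` and ``best_theta_``.
    """

    def __init__(
        self,
        template: OdeModelSpec | None = None,
        priors: PriorSpec | None = None,
        n_samples: int = 1000,
        top_n: int = 5,
        segment_len: int = 100,
        random_state: int = 0,
    ):
        self.template = template
        self.priors = priors
        self.n_samples = n_samples
        self.top_n = top_n
        self.segment_len = segment_len
        self.random_state = random_state

    def fit(self, X: SmoothedCurves, y=None) -> "AbcOdeFitter":
        if self.template is None:
            raise ValueError("a template OdeModelSpec is required")
        priors = self.priors or PriorSpec.from_families(self.template)
        self.result_ = abc_rejection(
            self.template, priors, X,
            n_samples=self.n_samples, seed=self.random_state,
            top_n=self.top_n, segment_len=self.segment_len,
        )
        self.best_spec_ = self.result_.best_spec
        self.best_theta_ = self.result_.best_theta
        return self

    def predict(self, X: SmoothedCurves) -> np.ndarray:
        """Piecewise simulation of the best accepted model against X's grid."""
        sim = simulate_piecewise(self.best_spec_, X, segment_len=self.segment_len)
        return sim.states
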