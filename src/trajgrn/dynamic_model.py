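"""ODE dynamic model of a gene network with switching rate schedules.

Each gene's expression x_i evolves as

    dx_i/dt = c_i + k_i(t) f_i(x) - d_i(t) x_i,

with basal synthesis c_i, maximal synthesis k_i, decay d_i, and a
Shea-Ackers (ratio of linear forms) regulatory function

    f_i(x) = (sum_j a_ij x_j) / (1 + sum_j b_ij x_j),

where a_ij > 0 encodes activation of gene i by gene j and a_ij = 0 with
b_ij > 0 pure repression (the term only inflates the denominator); a
nonzero a_ij requires a nonzero b_ij. Genetic switching along the
trajectory is modelled by piecewise-constant schedules multiplying k_i or
d_i by a factor A_i inside a time window: the "up-switch" preset (group 1)
raises k_i from the switch time onward, the "down-then-up" preset
(group 2) multiplies k_i in an early window and d_i in a late window.

The system is stiff over long horizons; simulation therefore proceeds in
consecutive segments of a fixed number of unit times, each restarted from
the observed (smoothed) expression at the segment's left endpoint, and an
implicit integrator (BDF) is used throughout. A failing segment is
surfaced as a recorded error, never a crash of the whole run.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateSchedule",
    "OdeModelSpec",
    "SimulatedTrajectory",
    "SegmentError",
    "regulatory_function",
    "rate_at",
    "simulate_segment",
    "simulate_piecewise",
]


class ModelSpecError(ValueError):
    """Structural violation of the model constraints."""


class SegmentError(RuntimeError):
    """Integrator failure on one segment; carries the segment bounds."""

    def __init__(self, t0: float, t1: float, message: str):
        super().__init__(f"integration failed on segment [{t0}, {t1}]: {message}")
        self.t0 = t0
        self.t1 = t1


@dataclass(frozen=True)
class RateSchedule:
    """Multiply one rate by ``multiplier`` on the window [t_start, t_end)."""

    rate: str  # "k" or "d"
    t_start: float
    t_end: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.rate not in ("k", "d"):
            raise ModelSpecError(f"schedule rate must be 'k' or 'd', got {self.rate!r}")
        if not self.t_start < self.t_end:
            raise ModelSpecError("schedule window must have t_start < t_end")
        if self.multiplier < 0:
            raise ModelSpecError("schedule multiplier must be nonnegative")

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class OdeModelSpec:
    """Rates, switching schedules and regulation matrices of the network.

    c, k0, d0, A : per-gene basal synthesis, maximal synthesis, decay and
        switch multiplier (A_i > 0; A_i > 1 for the up-switch preset).
    a, b : N x N nonnegative coefficient matrices of the regulatory
        function; b_ij == 0 forces a_ij == 0.
    schedules : per-gene list of :class:`RateSchedule`.
    groups : per-gene switching-pattern label (1, 2 or 0 for none), kept
        for bookkeeping when presets are applied.
    """

    c: np.ndarray
    k0: np.ndarray
    d0: np.ndarray
    A: np.ndarray
    a: np.ndarray
    b: np.ndarray
    schedules: list[list[RateSchedule]] = field(default_factory=list)
    groups: list[int] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.k0 = np.asarray(self.k0, dtype=float)
        self.d0 = np.asarray(self.d0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.n_genes
        for name, arr in (("c", self.c), ("k0", self.k0), ("d0", self.d0),
                          ("A", self.A)):
            if arr.shape != (n,):
                raise ModelSpecError(f"{name} must have shape ({n},)")
            if np.any(arr < 0):
                raise ModelSpecError(f"{name} must be nonnegative")
        if self.a.shape != (n, n) or self.b.shape != (n, n):
            raise ModelSpecError("a and b must be N x N")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ModelSpecError("a and b must be nonnegative")
        if np.any((self.b == 0) & (self.a > 0)):
            bad = np.argwhere((self.b == 0) & (self.a > 0))[0]
            raise ModelSpecError(
                f"a[{bad[0]},{bad[1]}] > 0 requires b[{bad[0]},{bad[1]}] > 0"
            )
        if not self.schedules:
            self.schedules = [[] for _ in range(n)]
        if len(self.schedules) != n:
            raise ModelSpecError("need one schedule list per gene")
        for i, scheds in enumerate(self.schedules):
            for rate in ("k", "d"):
                windows = sorted(
                    (s.t_start, s.t_end) for s in scheds if s.rate == rate
                )
                for (s0, e0), (s1, _) in zip(windows, windows[1:]):
                    if s1 < e0:
                        raise ModelSpecError(
                            f"overlapping {rate}-schedules for gene {i}"
                        )
        if self.gene_ids is None:
            self.gene_ids = [f"g{i}" for i in range(n)]

    @property
    def n_genes(self) -> int:
        return self.c.shape[0]

    # ---- switching presets -------------------------------------------------

    @classmethod
    def with_group_presets(
        cls,
        c, k0, d0, A, a, b,
        groups: list[int],
        t_up: float = 2500.0,
        k_window: tuple[float, float] = (500.0, 1000.0),
        d_window: tuple[float, float] = (2500.0, 3000.0),
        gene_ids: list[str] | None = None,
    ) -> "OdeModelSpec":
        """Build a spec with the two canonical switching patterns.

        Group 1 (low -> high): k_i = k_i0 for t < t_up, k_i0 * A_i after.
        Group 2 (high -> low -> high): k_i multiplied by A_i on
        ``k_window``, d_i multiplied by A_i on ``d_window``.
        """
        A = np.asarray(A, dtype=float)
        schedules: list[list[RateSchedule]] = []
        for i, g in enumerate(groups):
            if g == 1:
                schedules.append([RateSchedule("k", t_up, math.inf, A[i])])
            elif g == 2:
                schedules.append([
                    RateSchedule("k", k_window[0], k_window[1], A[i]),
                    RateSchedule("d", d_window[0], d_window[1], A[i]),
                ])
            elif g in (0, None):
                schedules.append([])
            else:
                raise ModelSpecError(f"unknown group {g!r} for gene {i}")
        return cls(c=c, k0=k0, d0=d0, A=A, a=a, b=b,
                   schedules=schedules, groups=list(groups), gene_ids=gene_ids)

    # ---- free-parameter plumbing (used by ABC and robustness) --------------

    _NAME_RE = re.compile(r"^(c|k0|d0|A)\[(\d+)\]$|^(a|b)\[(\d+),(\d+)\]$")

    def free_parameter_names(self) -> list[str]:
        """Names of the structurally free parameters.

        Per gene: c[i], k0[i], d0[i], A[i]; plus a[i,j] for every a_ij > 0
        and b[i,j] for every b_ij > 0 (absent regulations stay pinned at
        zero, so adding one auto-regulation a_ii, b_ii > 0 frees exactly
        two more parameters).
        """
        names = []
        n = self.n_genes
        for fam in ("c", "k0", "d0", "A"):
            names += [f"{fam}[{i}]" for i in range(n)]
        names += [f"a[{i},{j}]" for i in range(n) for j in range(n) if self.a[i, j] > 0]
        names += [f"b[{i},{j}]" for i in range(n) for j in range(n) if self.b[i, j] > 0]
        return names

    def get_parameter(self, name: str) -> float:
        m = self._NAME_RE.match(name)
        if not m:
            raise KeyError(name)
        if m.group(1):
            return float(getattr(self, m.group(1))[int(m.group(2))])
        return float(getattr(self, m.group(3))[int(m.group(4)), int(m.group(5))])

    def with_parameters(self, values: dict[str, float]) -> "OdeModelSpec":
        """Copy of the spec with the named parameters replaced.

        Schedules are rebuilt so a changed A_i propagates into its
        multiplier windows.
        """
        arrays = {f: getattr(self, f).copy() for f in ("c", "k0", "d0", "A", "a", "b")}
        for name, value in values.items():
            m = self._NAME_RE.match(name)
            if not m:
                raise KeyError(name)
            if m.group(1):
                arrays[m.group(1)][int(m.group(2))] = value
            else:
                arrays[m.group(3)][int(m.group(4)), int(m.group(5))] = value
        schedules = []
        for i, scheds in enumerate(self.schedules):
            old_A = self.A[i]
            new = []
            for s in scheds:
                mult = arrays["A"][i] if s.multiplier == old_A else s.multiplier
                new.append(replace(s, multiplier=mult))
            schedules.append(new)
        return OdeModelSpec(
            schedules=schedules, groups=self.groups,
            gene_ids=list(self.gene_ids), **arrays,
        )

    # ---- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": self.gene_ids,
                "c": self.c.tolist(),
                "k0": self.k0.tolist(),
                "d0": self.d0.tolist(),
                "A": self.A.tolist(),
                "a": self.a.tolist(),
                "b": self.b.tolist(),
                "groups": self.groups,
                "schedules": [
                    [
                        {"rate": s.rate, "t_start": s.t_start,
                         "t_end": None if math.isinf(s.t_end) else s.t_end,
                         "multiplier": s.multiplier}
                        for s in scheds
                    ]
                    for scheds in self.schedules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OdeModelSpec":
        d = json.loads(text)
        schedules = [
            [
                RateSchedule(s["rate"], s["t_start"],
                             math.inf if s["t_end"] is None else s["t_end"],
                             s["multiplier"])
                for s in scheds
            ]
            for scheds in d["schedules"]
        ]
        return cls(c=d["c"], k0=d["k0"], d0=d["d0"], A=d["A"], a=d["a"], b=d["b"],
                   schedules=schedules, groups=d.get("groups"),
                   gene_ids=d.get("gene_ids"))


@dataclass
class SimulatedTrajectory:
    """Simulation output on the unit-time grid.

    ``states[i, j]`` is gene i at ``times[j]``; failed segments carry NaN
    and are listed in ``failures`` as (t0, t1, message).
    """

    times: np.ndarray
    states: np.ndarray
    segment_bounds: list[tuple[float, float]]
    restarts: np.ndarray | None = None
    failures: list[tuple[float, float, str]] = field(default_factory=list)


def regulatory_function(x: np.ndarray, a_row: np.ndarray, b_row: np.ndarray) -> float:
    """Shea-Ackers regulatory input f = (a . x) / (1 + b . x)."""
    x = np.asarray(x, dtype=float)
    a_row = np.asarray(a_row, dtype=float)
    b_row = np.asarray(b_row, dtype=float)
    if np.any((b_row == 0) & (a_row > 0)):
        raise ModelSpecError("a > 0 requires the matching b > 0")
    return float(a_row @ x / (1.0 + b_row @ x))


def rate_at(t: float, base: float, schedules: list[RateSchedule]) -> float:
    """Effective rate at time t: base, or base * multiplier inside a window."""
    for s in schedules:
        if s.active(t):
            return base * s.multiplier
    return base


def _rates_vector(spec: OdeModelSpec, t: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.array([
        rate_at(t, spec.k0[i], [s for s in spec.schedules[i] if s.rate == "k"])
        for i in range(spec.n_genes)
    ])
    d = np.array([
        rate_at(t, spec.d0[i], [s for s in spec.schedules[i] if s.rate == "d"])
        for i in range(spec.n_genes)
    ])
    return k, d


def _rhs(spec: OdeModelSpec):
    a, b, c = spec.a, spec.b, spec.c

    def fun(t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)
        f = (a @ xc) / (1.0 + b @ xc)
        k, d = _rates_vector(spec, t)
        return c + k * f - d * x

    return fun


def _schedule_breaks(spec: OdeModelSpec, t0: float, t1: float) -> list[float]:
    pts = set()
    for scheds in spec.schedules:
        for s in scheds:
            for p in (s.t_start, s.t_end):
                if t0 < p < t1 and math.isfinite(p):
                    pts.add(p)
    return sorted(pts)


def simulate_segment(
    spec: OdeModelSpec,
    t0: float,
    t1: float,
    x0: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> SimulatedTrajectory:
    """Integrate one segment [t0, t1] from state x0, output on unit times.

    The integration is split internally at schedule discontinuities so
    the implicit solver never steps across a rate jump. Raises
    :class:`SegmentError` on integrator failure.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial condition must be nonnegative")
    grid = np.arange(math.ceil(t0), math.floor(t1) + 1, dtype=float)
    fun = _rhs(spec)
    breaks = [t0] + _schedule_breaks(spec, t0, t1) + [t1]
    states = np.empty((spec.n_genes, grid.size))
    x = x0.copy()
    for lo, hi in zip(breaks, breaks[1:]):
        mask = (grid >= lo) & (grid <= hi if hi == t1 else grid < hi)
        t_eval = np.unique(np.concatenate([grid[mask], [hi]]))
        sol = solve_ivp(fun, (lo, hi), x, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise SegmentError(t0, t1, sol.message)
        for tj, col in zip(sol.t, sol.y.T):
            hits = np.nonzero(grid == tj)[0]
            if hits.size and (tj < hi or hi == t1):
                states[:, hits[0]] = col
        x = sol.y[:, -1]
    states = np.maximum(states, 0.0)
    return SimulatedTrajectory(
        times=grid, states=states, segment_bounds=[(t0, t1)],
        restarts=x0[:, None],
    )


def simulate_piecewise(
    spec: OdeModelSpec,
    data,
    segment_len: int = 100,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SimulatedTrajectory:
    """Piecewise simulation restarted from observed data every segment.

    The horizon [0, T-1] (T = number of grid points in ``data``) is split
    into consecutive segments of ``segment_len`` unit times; each segment
    starts from the observed value at its left endpoint. A failing
    segment is recorded (its states become NaN) and the run continues.

    ``data`` is a :class:`~trajgrn.gp_smooth.SmoothedCurves` (or any
    object with ``grid`` and ``mean``).
    """
    if segment_len < 2:
        raise ValueError("segment_len must be >= 2")
    T = len(data.grid)
    horizon = T - 1
    times = np.arange(T, dtype=float)
    states = np.full((spec.n_genes, T), np.nan)
    bounds: list[tuple[float, float]] = []
    restarts = []
    failures: list[tuple[float, float, str]] = []
    start = 0
    while start < horizon:
        end = min(start + segment_len, horizon)
        x0 = np.maximum(np.asarray(data.mean)[:, start], 0.0)
        bounds.append((float(start), float(end)))
        restarts.append(x0)
        try:
            piece = simulate_segment(spec, start, end, x0, rtol=rtol, atol=atol)
        except SegmentError as exc:
            failures.append((float(start), float(end), str(exc)))
        else:
            # the restart value at `end` belongs to the next segment
            last = T if end == horizon else end
            states[:, start:last] = piece.states[:, : last - start]
        start = end
    return SimulatedTrajectory(
        times=times, states=states, segment_bounds=bounds,
        restarts=np.array(restarts).T if restarts else None, failures=failures,
    )
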