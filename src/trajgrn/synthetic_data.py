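"""Synthetic single-cell expression data with known latent pseudo-time.

Real single-cell qPCR snapshots come with no time axis: the generator
emulates that by laying gene profiles along a latent unit-time axis —
sigmoidal switches between low and high expression (one or two switch
events per gene, as observed for lineage-regulating transcription
factors), additive Gaussian noise, and a seeded random shuffle of the
cells so that the latent order must be re-discovered by the trajectory
stages. Datasets can also be generated from an ODE model spec, closing
the loop for network-inference and parameter-recovery benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dynamic_model import OdeModelSpec, simulate_segment
from .io_prep import ExpressionMatrix

__all__ = [
    "GeneProfile",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_profiles",
    "generate_from_ode",
    "default_spec",
]

PATTERNS = ("high_low", "low_high", "double_switch", "constant")


@dataclass
class GeneProfile:
    """Latent profile of one gene.

    pattern : one of "high_low", "low_high", "double_switch" (high ->
        low -> high) or "constant".
    switch_times : latent times of the switch event(s).
    sharpness : sigmoid width in latent units (smaller = sharper).
    baseline, amplitude : low level and high-minus-low span.
    """

    pattern: str
    switch_times: tuple[float, ...] = ()
    sharpness: float = 50.0
    baseline: float = 0.5
    amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern in ("high_low", "low_high") and len(self.switch_times) != 1:
            raise ValueError(f"{self.pattern} needs exactly one switch time")
        if self.pattern == "double_switch" and len(self.switch_times) != 2:
            raise ValueError("double_switch needs exactly two switch times")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.baseline, self.baseline + self.amplitude

        def up(t0):  # 0 -> 1 sigmoid centred at t0
            return 1.0 / (1.0 + np.exp(-(t - t0) / self.sharpness))

        if self.pattern == "constant":
            return np.full_like(t, lo)
        if self.pattern == "low_high":
            return lo + self.amplitude * up(self.switch_times[0])
        if self.pattern == "high_low":
            return hi - self.amplitude * up(self.switch_times[0])
        t0, t1 = self.switch_times  # high -> low -> high
        return hi - self.amplitude * up(t0) + self.amplitude * up(t1)


@dataclass
class SyntheticSpec:
    """Study conditions for the profile generator."""

    n_cells: int = 500
    profiles: list[GeneProfile] = field(default_factory=list)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for p in self.profiles:
            for st in p.switch_times:
                if not 0 < st < self.n_cells:
                    raise ValueError(
                        f"switch time {st} outside (0, {self.n_cells})"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.profiles)


@dataclass
class SyntheticDataset:
    """Generated matrix plus the ground truth needed to score recovery.

    ``latent_time[j]`` is the latent time of presented cell j (column j
    of the matrix); ``shuffle[r]`` is the presented column holding the
    cell with latent time r, so ``latent_time[shuffle] == arange(N)``.
    """

    matrix: ExpressionMatrix
    latent_time: np.ndarray
    shuffle: np.ndarray
    patterns: list[str] | None = None
    true_spec: OdeModelSpec | None = None
    noiseless: np.ndarray | None = None

    def ground_truth_json(self) -> str:
        payload = {
            "latent_time": self.latent_time.tolist(),
            "shuffle": self.shuffle.tolist(),
            "patterns": self.patterns,
        }
        if self.true_spec is not None:
            payload["true_spec"] = json.loads(self.true_spec.to_json())
        return json.dumps(payload, indent=2)


def default_spec(n_cells: int = 500, n_genes: int = 12, noise_sd: float = 0.3,
                 seed: int = 0) -> SyntheticSpec:
    """Desk-scale default: a mix of up-, down- and double-switch genes.

    Switch times are spread over the horizon and the sigmoid width is
    ~10% of it, mimicking the sharp transitions seen in lineage data.
    The last gene is constant (a housekeeping-like profile that
    exercises the variance filter upstream).
    """
    sharp = 0.02 * n_cells  # 10% switch width (~5 sigmoid widths)
    profiles = []
    kinds = ["low_high", "high_low", "double_switch"]
    for g in range(n_genes - 1):
        kind = kinds[g % 3]
        frac = 0.25 + 0.5 * (g // 3) / max(1, (n_genes - 2) // 3)
        if kind == "double_switch":
            times = (0.3 * n_cells, min(0.9, frac + 0.35) * n_cells)
        else:
            times = (frac * n_cells,)
        profiles.append(GeneProfile(
            pattern=kind, switch_times=times, sharpness=sharp,
            baseline=0.5 + 0.1 * (g % 5), amplitude=3.0 + 0.5 * (g % 4),
        ))
    profiles.append(GeneProfile(pattern="constant", baseline=1.0, amplitude=0.0))
    return SyntheticSpec(n_cells=n_cells, profiles=profiles,
                         noise_sd=noise_sd, seed=seed)


def example_cascade_spec(slow: bool = True) -> OdeModelSpec:
    """A 3-gene activation cascade (g0 -> g1 -> g2) used as the standard
    small ODE benchmark: saturating activation on both edges, slow decay
    so the genes sweep a wide dynamic range over a few hundred unit times.
    """
    a = np.zeros((3, 3))
    b = np.zeros((3, 3))
    a[1, 0], b[1, 0] = 1.0, 0.5
    a[2, 1], b[2, 1] = 0.8, 0.5
    return OdeModelSpec(
        c=[0.5, 0.2, 0.2],
        k0=[1.5, 2.0, 1.8],
        d0=[0.05, 0.04, 0.05],
        A=[1.0, 1.0, 1.0],
        a=a,
        b=b,
    )


def _package(
    values_latent: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    patterns: list[str] | None = None,
    true_spec: OdeModelSpec | None = None,
    gene_ids: list[str] | None = None,
    shuffled: bool = True,
) -> SyntheticDataset:
    n_genes, n_cells = values_latent.shape
    noisy = values_latent + rng.normal(0.0, noise_sd, size=values_latent.shape)
    if shuffled:
        shuffle = rng.permutation(n_cells)
    else:
        shuffle = np.arange(n_cells)
    presented = np.empty_like(noisy)
    presented[:, shuffle] = noisy  # column shuffle[r] holds latent time r
    latent_time = np.empty(n_cells, dtype=int)
    latent_time[shuffle] = np.arange(n_cells)
    if gene_ids is None:
        gene_ids = [f"g{i:02d}" for i in range(n_genes)]
    matrix = ExpressionMatrix(
        values=presented,
        gene_ids=gene_ids,
        cell_ids=[f"c{j:04d}" for j in range(n_cells)],
        housekeeping=np.zeros(n_genes, dtype=bool),
    )
    return SyntheticDataset(
        matrix=matrix, latent_time=latent_time, shuffle=shuffle,
        patterns=patterns, true_spec=true_spec, noiseless=values_latent,
    )


def generate_profiles(spec: SyntheticSpec, shuffled: bool = True) -> SyntheticDataset:
    """Sigmoid-switch profiles + noise, cells presented in random order."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_cells, dtype=float)
    values = np.vstack([p.evaluate(t) for p in spec.profiles])
    return _package(
        values, spec.noise_sd, rng,
        patterns=[p.pattern for p in spec.profiles], shuffled=shuffled,
    )


def generate_from_ode(
    spec: OdeModelSpec,
    n_cells: int,
    x0: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    shuffled: bool = True,
) -> SyntheticDataset:
    """Simulate the ODE model over [0, n_cells - 1] and sample one cell
    per unit time; ground-truth spec attached for recovery benchmarks."""
    sim = simulate_segment(spec, 0.0, float(n_cells - 1), np.asarray(x0, float))
    rng = np.random.default_rng(seed)
    return _package(
        sim.states, noise_sd, rng, true_spec=spec,
        gene_ids=list(spec.gene_ids), shuffled=shuffled,
    )
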