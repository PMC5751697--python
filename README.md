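# trajgrn

Reverse-engineering gene regulatory dynamics from single-cell expression
snapshots.

Single-cell qPCR (or similar) measurements give a genes × cells matrix of
expression values, but no time axis: each cell is destroyed when measured,
so a developmental process is observed only as an unordered collection of
snapshots. `trajgrn` reconstructs the missing axis and uses it to fit an
executable model of the underlying gene network, in four stages:

1. **Pseudo-temporal ordering.** Cells are embedded with a diffusion map
   (Gaussian kernel `W_ij = exp(-||x_i - x_j||² / 2ε)`, row-normalized to
   a Markov matrix, leading non-trivial eigenvectors) and ordered along
   the developmental continuum with the Wanderlust algorithm: an ensemble
   of `l`-out-of-`k` nearest-neighbour graphs, landmark-weighted shortest
   paths, and iterative re-orientation until scores converge. The
   resulting pseudo-time puts `N` cells on the unit-time grid `0 … N-1`.
2. **Expression smoothing.** Each gene's noisy profile along pseudo-time
   is smoothed by Gaussian-process regression under a squared-exponential
   kernel, with hyperparameters fitted by marginal-likelihood
   maximization; the posterior mean on the full grid is the gene's curve.
3. **Network inference.** A GENIE3-style random-forest ensemble scores
   every directed gene pair (each target regressed on all other genes at
   the previous unit time), and the `N(N-1)` candidate edges are pruned in
   two stages: top-`k` incoming edges per target, then a global weight
   threshold (optionally auto-chosen as the largest threshold keeping all
   genes connected).
4. **Dynamic modelling.** The pruned network is instantiated as a
   Shea–Ackers-style ODE system,
   `dx_i/dt = c_i + k_i(t)·(Σ_j a_ij x_j)/(1 + Σ_j b_ij x_j) - d_i(t)·x_i`,
   with optional stepwise rate schedules. Parameters are fitted by ABC
   rejection sampling: candidates drawn from uniform priors, simulated
   piecewise (restarting from the data every 100 unit times), scored by
   the relative absolute error `E = Σ_i Σ_j |x_ij - x*_ij| / max_j{x*_ij}`
   and the segment transfer probability `L(θ) = Π_i 1/E_i`, with the
   top-ranked parameter sets accepted. A perturbation-ensemble robustness
   analysis (multiplicative `Uniform(1-m, 1+m)` noise on each parameter)
   then discriminates among near-equally-fitting models.

A synthetic-data generator (sigmoidal switch profiles with a known latent
ordering, or trajectories simulated from a known ODE model) closes the
loop for end-to-end validation.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import trajgrn as tg
from trajgrn.synthetic_data import default_spec

# 500 shuffled cells x 12 genes of noisy switch-like profiles
ds = tg.generate_profiles(default_spec(n_cells=500, n_genes=12,
                                       noise_sd=0.3, seed=1))
shifted = tg.shift_to_nonnegative(ds.matrix)

dm = tg.DiffusionMap(n_components=3).fit(shifted.values.T)
print(dm.epsilon_, dm.eigenvalues_)
# 65.133 [0.275  0.1528 0.0497]

traj = tg.order_cells(dm.embedding_, seed=1)
print(traj.n_iterations,
      spearmanr(traj.pseudotime, ds.latent_time).statistic)
# 2 -0.988        <- recovered ordering vs hidden ground truth

curves = tg.smooth_all_genes(traj, shifted, subsample=4)
net = tg.Genie3Network(n_trees=200, top_per_gene=3, threshold="auto",
                       random_state=0).fit(curves.mean,
                                           gene_ids=list(shifted.gene_ids))
print(net.scores_.n_candidates, len(net.network_.stage1_edges),
      len(net.network_.edges))
# 132 36 27       <- candidates, after stage 1, after stage 2
```

Fitting and robustness, on a 3-gene activation cascade with known truth:

```python
from trajgrn.abc_fit import PriorSpec, abc_rejection
from trajgrn.robustness import robustness_metrics
from trajgrn.synthetic_data import example_cascade_spec
from trajgrn.gp_smooth import SmoothedCurves

spec = example_cascade_spec()
sim = tg.generate_from_ode(spec, 200, x0=[0.5, 0.5, 0.5], shuffled=False)
obs = SmoothedCurves(grid=np.arange(200.0), mean=sim.noiseless,
                     variance=np.zeros_like(sim.noiseless),
                     gene_ids=list(spec.gene_ids))

names = [f"{f}[{g}]" for f in ("k0", "d0") for g in range(3)]
priors = PriorSpec.around(spec, names, rel_width=0.3)
res = abc_rejection(spec, priors, obs, n_samples=300, seed=11, top_n=5)
# best draw recovers every rate within 20% of the generating value

report = robustness_metrics(spec, res.best_theta, obs, n=1000, magnitude=0.1)
print(report.mean_error, report.excluded_fraction)
```

## Command-line pipeline

Every stage is also a subcommand of the `trajgrn` CLI, reading and
writing plain-text artifacts (TSV/JSON) under one output directory and
driven by a YAML config plus a global seed:

```bash
trajgrn --seed 1 all --with-simulated-data   # full pipeline
trajgrn --config my.yaml prep                # single stage
```

Stage outputs carry `.meta.json` sidecars with the config hash;
re-running an unchanged stage is a no-op unless `--force` is given.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers every module with hand-computed oracles (closed-form GP
posteriors, brute-force shortest paths, exact pruning scans, analytic
ODE solutions) plus property-based invariants, and
`tests/test_acceptance.py` re-derives the headline end-to-end claims.

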