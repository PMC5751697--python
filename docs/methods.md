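# Methods

This document describes the model and procedure implemented in each
module, the parameters and their defaults, the numerical choices, and the
package's known limitations. Notation: the data is a genes × cells matrix
`X` of relative expression values (e.g. qPCR dCt, higher = more
expressed); `N` cells, `G` genes.

## 1. Input preparation (`trajgrn.io_prep`)

- **Loading.** Expression matrices are read from TSV/CSV with genes as
  rows and cells as columns, plus a gene annotation table flagging
  housekeeping (normalization-control) genes. Malformed cells raise
  `ParseError` with the offending row/column.
- **Gene filtering** removes (a) housekeeping genes, which carry
  normalization rather than regulatory signal, (b) explicitly excluded
  gene IDs, and (c) genes whose variance falls below `variance_floor`
  (default 0, i.e. only exactly-constant genes). Gene order is preserved.
- **Nonnegative shift.** Downstream models require nonnegative
  expression. Each gene's row minimum is subtracted, which guarantees an
  exact zero minimum per gene regardless of the sign of the original
  minimum. The per-gene offsets and the convention string are recorded so
  the transform is invertible.

## 2. Diffusion-map embedding (`trajgrn.diffusion_map`)

Cells are points in `G`-dimensional expression space. The Gaussian kernel

    W_ij = exp(-||x_i - x_j||^2 / (2 eps)),

is row-normalized into a Markov transition matrix `M = W / P`
(`P` = row sums). The embedding uses the leading eigenvectors of `M`,
computed stably via the symmetric conjugate `S = D^{-1/2} W D^{-1/2}`
(same spectrum, orthogonal eigenvectors, `scipy.linalg.eigh`), dropping
the trivial stationary eigenpair (eigenvalue 1). Signs are fixed so the
largest-magnitude entry of each component is positive, making the
embedding deterministic.

Parameters: `n_components` (default 3 — enough to separate a
one-dimensional developmental continuum plus branching), `epsilon`
(default `"median"`: the median squared pairwise distance, a standard
scale-free bandwidth choice).

## 3. Wanderlust ordering (`trajgrn.wanderlust`)

The embedding is ordered with the Wanderlust algorithm:

- **Graph ensemble.** `n_graphs` (default 5) `l`-out-of-`k`
  nearest-neighbour graphs: for each cell, `l` (default 15) neighbours
  are sampled uniformly from its `k` (default 30) nearest. Subsampling
  makes the ensemble robust to short-circuit edges. Edges are weighted by
  Euclidean distance; shortest paths (Dijkstra) treat edges as
  undirected, which guarantees the connectivity a directed subsampled
  graph cannot (the out-degree-`l` structure is otherwise preserved).
- **Landmarks.** `n_landmarks` (default 20) cells drawn once per run
  (excluding the start cell). Landmark `l`'s contribution to cell `t` is
  weighted by `w_{l,t} = d(l,t)^2 / sum_m d(l,m)^2`, the sum running over
  landmarks; when that normalizer is zero (single landmark at zero
  distance) the weight degenerates to 1 so scores reduce to plain
  distances.
- **Scores.** `Score_t = sum_l sign * (d(l,t)/n_l) * w_{l,t}`, the sign
  negative when `t` precedes landmark `l` (first pass: `d(s,t) < d(s,l)`
  from the start cell; later passes use the previous iteration's scores).
  Iteration stops when range-normalized landmark scores move less than
  `tol` (default 1e-3; cap `max_iter` = 50), and scores are averaged over
  the graph ensemble.
- **Start cell.** `"auto"` picks the cell with the largest absolute
  first diffusion coordinate — an extreme of the main continuum. The
  final ranking places `N` cells on the unit-time grid `0 … N-1`
  (`horizon = N - 1`); ties break deterministically by cell index.

The orientation of the axis is arbitrary (pseudo-time may come out
reversed); accuracy is therefore measured by absolute Spearman
correlation against ground truth where available.

## 4. Gaussian-process smoothing (`trajgrn.gp_smooth`)

Each gene's profile along pseudo-time is modelled as
`y = f(t) + eps, eps ~ N(0, sigma_n^2)` with a GP prior on `f` under the
squared-exponential kernel `K(t,t') = sigma^2 exp(-(t-t')^2 / 2 l^2)`.
The posterior mean/variance are computed with a Cholesky solve of
`K + sigma_n^2 I` (jitter 1e-8 for the noise-free limit). Targets are
centred before fitting (the prior has zero mean, so uncentred profiles
would shrink toward zero away from data). Hyperparameters are fitted per
gene by L-BFGS-B maximization of the log marginal likelihood over
log-parameters, started at `(var(y), span/10, 0.1·var(y))`. For long
trajectories the training set is evenly subsampled (default every 4th
cell — the solve is cubic in training size only; the posterior is still
evaluated on the full grid).

## 5. Network inference (`trajgrn.grn_inference`)

A GENIE3-style ensemble adapted to ordered data: for each target gene, a
random forest (default 1000 trees, `sqrt` feature subsampling,
scikit-learn implementation) regresses the target at unit time `t+1` on
all other genes at time `t`; normalized feature importances are the
directed edge weights. Constant targets contribute zero importances.
The `G(G-1)` candidates are pruned in two stages:

1. keep the `top_per_gene` (default 10) strongest incoming edges per
   target;
2. drop edges with weight ≤ `threshold`. `threshold="auto"` picks the
   largest threshold that keeps every gene incident to at least one
   surviving edge; `threshold=0` makes stage 2 a no-op.

An undirected view collapses reciprocal edges to their maximum weight.

## 6. Dynamic model (`trajgrn.dynamic_model`)

Each gene follows

    dx_i/dt = c_i + k_i(t) * f_i(x) - d_i(t) * x_i,
    f_i(x)  = (sum_j a_ij x_j) / (1 + sum_j b_ij x_j),

a Shea–Ackers-style saturating regulation function (`a_ij` activation
strengths, `b_ij` binding terms; `b_ij = 0` forces `a_ij = 0`, since an
activation term without a binding term is not physically meaningful and
would make `f` unbounded). `c_i` is basal production, `k_i`/`d_i` are
production/degradation rates which may follow stepwise **rate
schedules** — windows `[t_start, t_end)` multiplying the base rate, with
convenience presets for genes whose rates switch up permanently
(multiplier `A_i` on `k` from `t_up` on, default 2500) or transiently
(windows on `k` and `d`, defaults (500, 1000) and (2500, 3000)).

Integration uses `scipy.integrate.solve_ivp` (BDF, rtol 1e-6,
atol 1e-9), splitting internally at schedule discontinuities so the
stiff solver never steps across a jump. **Piecewise simulation** against
observed curves restarts from the observed values every `segment_len`
(default 100) unit times — long horizons would otherwise let small rate
errors compound; a failed segment is recorded (states set to NaN) and
the run continues.

## 7. ABC fitting (`trajgrn.abc_fit`)

Parameters are drawn from independent uniform priors (`PriorSpec`):
per-family default boxes over broad positive ranges, or multiplicative
boxes `[(1-w)θ, (1+w)θ]` around a reference for recovery studies. Each
draw is simulated piecewise and scored by

- the relative absolute error
  `E = sum_i sum_j |x_ij - x*_ij| / max_j{x*_ij}`, each gene normalized
  by its **maximum observed value** — a candidate-dependent normalizer
  would make errors incomparable across draws; and
- the segment transfer probability `L(θ) = prod_i 1/E_i` over per-segment
  errors (zero segment error ⇒ +inf, flagged as an exact fit).

Draws are ranked by ascending `E` (failed simulations get infinite error
and never abort the run) and the `top_n` (default 5) are accepted. The
robustness analysis then discriminates among them.

## 8. Robustness (`trajgrn.robustness`)

Each free parameter is multiplied by an independent
`Uniform(1-m, 1+m)` draw (default magnitude `m = 0.1`; values clip at 0,
flagged); the perturbed model is simulated and scored against the
**unperturbed reference simulation** (not the data) with the same
relative error. Over `n` (default 1000) perturbations the report gives
mean and variance of the error and the fraction of excluded (failed)
runs. Lower mean/variance = flatter error landscape = a more robust,
hence preferable, fitted model.

## 9. Synthetic data (`trajgrn.synthetic_data`)

Two generators close the validation loop:

- **Profile generator:** genes follow sigmoidal switch profiles along a
  latent unit-time axis — `low_high`, `high_low`, `double_switch`
  (high→low→high) or `constant` — with additive Gaussian noise and a
  seeded shuffle of the cells, so the latent order must be re-discovered.
  The default panel (500 cells × 12 genes, noise SD 0.3, switch width 2%
  of the horizon, one constant gene) emulates the qualitative structure
  of lineage-factor expression: sharp switch events at different times,
  heterogeneous baselines/amplitudes, and a housekeeping-like profile.
  It does **not** emulate qPCR detection limits, dropouts, branching
  trajectories, or correlated (cell-wise) noise.
- **ODE generator:** simulates a known `OdeModelSpec` and samples one
  cell per unit time, attaching the generating spec as ground truth. The
  standard benchmark is a 3-gene activation cascade
  (`example_cascade_spec`).

## 10. CLI (`trajgrn.cli`)

Each stage is a subcommand writing plain-text artifacts (TSV/JSON) under
one output directory, driven by a YAML config merged over documented
defaults and a global seed. Artifacts carry `.meta.json` sidecars with
the config hash; re-running an unchanged stage is a no-op unless
`--force`. `all` chains data → prep → embed → order → smooth →
infer-grn → fit-ode → robustness; without an externally fitted topology,
`fit-ode` instantiates its ODE template from the pruned network
(saturating activation with order-one rates, which the priors then
explore).

## Design choices on underdetermined points

- The landmark-weight normalizer sums over landmarks (not all cells):
  weights then compare each landmark's proximity to `t` against its
  proximity to the other landmarks, keeping the score scale-free.
- Shortest paths symmetrize the subsampled graph (see §3).
- The error normalizer uses observed maxima (see §7).
- The nonnegative shift subtracts the row minimum rather than adding its
  absolute value, so the invariant "each gene's minimum is exactly 0"
  holds for all-positive rows too.
- Rate-schedule windows are half-open `[t_start, t_end)`, so a
  permanent up-switch at `t_up` is active at `t_up` itself.

## Problem sizes and benchmarks

The shipped defaults are desk-scale (500 cells × 12 genes for profile
studies; 200 unit times × 3 genes for fitting benchmarks), chosen so the
full suite and the acceptance script run in minutes on one CPU. All
algorithms are dimension-generic; documented complexity hot spots are
the O(N²) kernel/eigendecomposition, the cubic GP solve (mitigated by
subsampling), and the per-draw ODE simulation in ABC.

## Limitations

- Wanderlust assumes a single non-branching trajectory; branching fates
  need upstream gating or a branching-aware ordering.
- Pseudo-time orientation is arbitrary (sign ambiguity).
- Rejection ABC with a few hundred draws has visible Monte-Carlo spread:
  on the cascade benchmark with ±30% priors and 300 draws, the
  worst-coordinate recovery error of the best draw ranges roughly
  10–30% across seeds. Tighter recovery needs more draws or sequential
  schemes.
- The relative-error score weights all genes and times equally; the GP
  posterior variance is reported but not yet used to weight the fit.
- The random-forest inference detects (possibly lagged) statistical
  dependence, not causality; strongly correlated co-regulated genes can
  swap edge directions.
- The ODE model is deterministic; stochastic gene expression is only
  represented through the additive noise of the synthetic generator.
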