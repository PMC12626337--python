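# Methods

## Model

The community is modeled by the generalized Lotka-Volterra (gLV) system
for m species,

    dN_i/dt = N_i ( r_i + Σ_j b_ij N_j ),

with per-capita growth rates r_i (1/time) and pairwise interaction
coefficients b_ij (1/(abundance·time)).  Writing N_sum = Σ_i N_i and
x_i = N_i / N_sum, the equivalent relative-coordinate system is

    dN_sum/dt = Σ_i ( r_i x_i N_sum + Σ_j b_ij x_i x_j N_sum² )
    dx_i/dt   = ( r_i x_i N_sum + Σ_j b_ij x_i x_j N_sum² − x_i dN_sum/dt ) / N_sum ,

in which Σ_i dx_i/dt = 0 identically, so the compositional state stays
on the simplex.  Only x is observed; N_sum is latent.

Two identifiability facts shape the estimators.  Substituting the
simplex constraint into the log-gradient regression shows that from
compositions only r_i + b_i1 and the differences b_ij − b_i1 are
determined: the diagonal b_ii cannot be separated, so every
relative-input method pins b_ii = 0.  Second, replacing the
total-abundance guess c·N_sum_guess for N_sum_guess leaves the r
estimate unchanged and rescales B by 1/c — B is identified only up to a
positive gauge constant.  Recovery is therefore scored by the cosine of
the concatenated off-diagonal b_ij, which is invariant to that gauge.

## Estimators

**Gradient matching (baselines).**  The log-derivative identity
d(ln N_i)/dt = r_i + Σ_j b_ij N_j is discretized with forward
differences on the sampling grid (non-uniform grids supported) and fit
by one OLS regression per species; regressor abundances are taken at
the left endpoint of each interval (a midpoint-average option exists;
it shifts baseline cosines slightly).  Applied to absolute abundances
this is `gLV_absolute` (self columns optional); applied directly to
compositions with self columns removed it is `gLV_relative`.  Values
are clipped at 1e-6 before the log.  The compositional-LV surrogate
regresses log-gradients of x_i/x_D on {x_j, j ≠ D} against a reference
species D of minimal sample variance (ties → lowest index) and is
scored only through the contrast directions b_ij − b_Dj; it does not
reproduce the original cLV fitting machinery, so its scores are
reference magnitudes rather than exact reproductions.  Pearson/Spearman
correlation matrices (diagonal zeroed) serve as deliberately naive
baselines.

**iLV.**  Subroutine 1 forms pseudo-absolute abundances N⁰ = X·guess,
fits the regression above (self columns excluded), then loops up to
M = 100 times: simulate the relative-coordinate system from the first
observed row with N_sum(0) = guess, record the trajectory RMSE of the
current iterate, rescale X by the simulated N_sum(t) path (clipped to
[1e-6, 1e8]) and re-fit.  Iterations are numbered from 1 (= the
constant-total estimate); the minimum-RMSE iterate is the warm start,
so the selected RMSE never exceeds the plain linear-approximation fit.
An invalid iterate scores +inf and the loop continues with the guess as
a flat fallback path.

Subroutine 2 minimizes 0.5·Σ f², f = vec(X_obs − X_sim), over
{r_i, b_ij (i≠j), x(0)}; N_sum(0) stays fixed at the guess (it is the
gauge).  x(0) enters the integrator unprojected — the optimizer explores
it freely — and only the returned estimate is clipped/renormalized to
the simplex.  Three backends run from the same start: `lm-a`
(`scipy.optimize.leastsq`), `lm-b` (`least_squares(method="lm")`) and
`trf` (`least_squares(method="trf")` with box [−1, 1] on coefficients
and [0, 1] on x(0)); a dogbox-style backend is excluded for poor
stability.  The untouched start is always a candidate and the lowest
trajectory RMSE wins, so refinement can never make the fit worse.  The
restart wrapper repeats subroutine 2 from multiplicatively jittered
warm starts ((1+δ) elementwise, δ ~ N(0, 0.05), restart 0 unjittered,
per-restart seeds) and keeps the best result; jitter is the explicit,
reproducible stand-in for the run-to-run variability that repeated
optimizer runs otherwise exhibit for unexplained reasons.  Restarts
stop early once the best RMSE falls below 1e-8 (= the integration
tolerance): below that level residuals are solver noise and further
restarts cannot improve the fit (disable with `early_stop_rmse=0`).

## Numerical choices

* Integration: LSODA (`scipy.integrate.odeint`), rtol = atol = 1e-8,
  default step cap (500 per output interval).  Reported composition
  rows are renormalized (pre-normalization drift ≲ 1e-6); raw solver
  states are kept for diagnostics.
* Failure handling: when LSODA aborts mid-way its output rows beyond
  the failure point are **uninitialized memory**; they are overwritten
  with NaN (detected from the per-output integration times).  Without
  this, any quantity touching a failed trajectory silently depends on
  what the process computed earlier — cost landscapes and "stuck"
  optimizer endpoints become irreproducible.  This handling makes every
  pipeline output bit-reproducible under fixed seeds.  A notable
  consequence: started from the raw constant-total estimate on the
  coarse long-grid periodic dataset, Levenberg-Marquardt *converges* to
  a near-exact fit (~5e-11) instead of stalling around 0.12–0.2 the way
  it does when finite garbage steers the line search; stalled endpoints of the
  no-warm-start variant are an artifact of that garbage, not a property
  of the cost landscape.
* Inside the least-squares residual, non-finite entries are replaced by
  a flat 1e3 penalty per entry, preserving the finite part of the
  residual vector; each optimizer run is capped at 1000 residual
  evaluations (converging fits use a few hundred; the cap bounds
  hopeless wanders through failure plateaus).
* Trajectory RMSE includes the t = 0 term (after x(0) is optimized its
  residual is generally nonzero) and is +inf only when the simulated
  compositions are non-finite.  A finite composition path whose latent
  total overflows (|N_sum| > 1e8, flagged as `blowup`) is still scored:
  the compositional fit is well-defined regardless of the
  unidentifiable total's magnitude.
* Undefined cosines (zero vector) return NaN with a warning so
  benchmark tables can render missing cells.

## Synthetic data

Two 3-species presets anchor the benchmarks, both started from
x(0) = (0.3, 0.5, 0.2), N_sum(0) = 100 on the grid 0..10 step 1 unless
overridden: *periodic* (r = (0.31, −0.6, 0.29); b12 = −0.01,
b13 = 0.011, b21 = 0.009, b23 = −0.01, b31 = −0.012, b32 = 0.015),
whose oscillations resemble predator-prey cycling, and *stabilizing*
(r = (0.21, −0.4, 0.19); b12 = −0.02, b13 = 0.016, b21 = 0.01,
b23 = −0.014, b31 = −0.017, b32 = 0.02), in which one species comes to
dominate.  Self-interaction variants add negative diagonals at three
magnitudes (low/medium/high density dependence, e.g. high periodic:
−0.012, −0.014, −0.011).  Two further presets reproduce the
optimizer-instability design (periodic with r2 = +0.6, Δt = 0.4,
t = 20) and the subroutine-ablation design (periodic, Δt = 1, t = 20).

Noise is multiplicative Gaussian on the relative abundances — each
entry times (1 + ε), ε ~ N(0, level) with level 0.05 or 0.10 — followed
by clipping at 1e-6 and row renormalization, so observations remain
compositions; an additive mode is available behind a switch.
Multiplicative-then-renormalize was chosen because compositions must
stay on the simplex and proportional error is the natural regime for
abundance data; renormalization keeps it near-unbiased (per-entry mean
within 1% at level 0.05).  Replicate seeds derive deterministically
from (scenario seed, replicate index).

What the generator does *not* emulate: sequencing-count noise
(multinomial/Dirichlet sampling, zero inflation), compositional zeros,
taxonomic aggregation effects, or perturbations/antibiotics.  Passing
tests on these synthetic designs therefore demonstrate correctness of
the estimation machinery under the stated noise model, not performance
on raw sequencing data.

## Benchmark protocol

For each design point (scenario × grid × noise level) the harness
generates seeded replicates (20 in the full design; desk-scale runs use
5), fits every requested method, and aggregates the recovery cosine
(mean and SD over replicates; single values without SD in noise-free
cells).  The absolute-data baseline consumes the noisy compositions
rescaled by the clean simulated N_sum path — how its input should be
noised is genuinely underdetermined, so this choice is explicit and
switchable.  Method comparison uses a Friedman omnibus test over the
paired per-replicate scores followed, at p < 0.05, by one-sided
Wilcoxon signed-rank tests of the best-mean method against each
competitor; a method is flagged best only if it beats all others at
p < 0.05.  Raw p-values are reported (the convention in such benchmark tables);
a Holm-corrected column is emitted alongside.  On exchangeable null
tables the best-flag rate stays at the nominal level (≤ 7% observed
over 1000 simulated tables).

Real-data evaluation uses repeated random train/validation splits of
the time points.  Index 0 is always assigned to training because the
ODE needs its anchor (whether the original analyses forced this is
unknown; without the anchor a validation-only initial point would make
simulation ill-posed).  Each method fits on training residuals only,
the trajectory is simulated from t = 0, and RMSE is evaluated
separately on the two index sets.  The log-ratio contrast method is
excluded by construction — it cannot produce trajectories.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the 3-species presets at
their preset designs (11–101 time points), with 5 noisy replicates ×
5 restarts for the noisy-recovery summary and 1000 simulated tables for
the significance-protocol calibration.  These sizes were chosen so the
whole validation runs in minutes on one CPU while leaving every
reported quantity stable at its stated tolerance.

## Known limitations

* Finite-difference Jacobians throughout; fine at m ≤ 5, wasteful for
  large communities (sensitivity equations are out of scope).
* The restart jitter is a modeling choice, not a reproduction of any
  particular source of run-to-run variability; quantities that depend
  on it (stability-report spreads) are qualitative.
* `nsum_guess` matters in practice for real datasets (scan a few orders
  of magnitude; the trajectory RMSE is flat for small systems but grows
  more sensitive with system size).
* No regularization: dense noisy systems with many taxa will overfit;
  ridge/lasso variants are out of scope.
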