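# ilvkit

Inference of generalized Lotka-Volterra (gLV) growth and interaction
coefficients from **compositional** (relative-abundance) time series.

Sequencing-based microbiome surveys measure the *fractions* of a
community occupied by each taxon, not absolute cell counts.  The classic
gLV model

```
dN_i/dt = N_i ( r_i + Σ_j b_ij N_j )
```

needs absolute abundances `N_i` for parameterisation, so it cannot be fit
directly to such data.  `ilvkit` implements the **iterative
Lotka-Volterra (iLV)** estimator, which rewrites the gLV system in
relative abundances `x_i = N_i / N_sum` plus the latent community total
`N_sum`, and estimates `r_i` and the off-diagonal `b_ij` from the
compositions alone:

1. **Iterative subroutine** — pretend `N_sum` is constant at a
   user-supplied guess, fit the log-gradient linear regression
   `Δ(ln N_i)/Δt ≈ r_i + Σ_j b_ij N_j`, then repeatedly re-simulate the
   latent `N_sum(t)` path under the current parameters, rescale the
   observed compositions into refreshed pseudo-absolute abundances and
   re-fit.  The minimum-RMSE iterate becomes the warm start.
2. **Least-squares subroutine** — nonlinear least squares on the stacked
   residuals (observed minus ODE-simulated relative abundances), run
   from that warm start through three optimizer backends (two
   Levenberg-Marquardt variants and a bounded trust-region-reflective
   variant); the best candidate by trajectory RMSE wins, over a set of
   seeded jittered restarts.

From compositions the interaction matrix is identifiable only up to a
positive constant (the `N_sum` scale gauge) and the diagonal `b_ii` not
at all, so the diagonal is pinned to zero and recovery is scored by the
**cosine similarity of the concatenated off-diagonal `b_ij`**, which is
invariant to the gauge.  Trajectory fit is scored by the RMSE between
observed and model-simulated relative abundances over all species and
sampled time points.

The package also ships everything needed to validate the method: a
simulator with named 3-species benchmark presets (periodic
oscillations and a stabilizing community, with optional self-interaction
diagonals and multiplicative Gaussian noise), the gradient-matching
baselines (`gLV_absolute`, `gLV_relative`, a log-ratio contrast
surrogate of the compositional-LV approach, Pearson/Spearman
correlations), the Friedman + one-sided Wilcoxon comparison protocol,
train/validation splitting for real datasets, and an interaction-network
extraction rule.

## Worked example

Estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`, trailing-underscore fitted attributes):

```python
import numpy as np
from ilvkit import ILVRegressor, cosine_offdiag, generate_dataset, make_scenario

# 3-species periodic community, 11 time points, 5% multiplicative noise
scenario = make_scenario("periodic", noise_level=0.05, n_replicates=1, seed=42)
series, truth = generate_dataset(scenario)

est = ILVRegressor(nsum_guess=200, restarts=5, random_state=0)
est.fit(series.X, series.times)

print(f"trajectory RMSE : {est.rmse_:.4f}")
print(f"winning backend : {est.backend_} (restart {est.restart_})")
print(f"growth rates    : {np.round(est.r_, 3)}")
print(f"cosine vs truth : {cosine_offdiag(est.B_, truth.B):.3f}")
```

prints

```
trajectory RMSE : 0.0096
winning backend : trf (restart 1)
growth rates    : [ 0.095 -0.653  0.488]
cosine vs truth : 0.890
```

The fitted model reproduces the noisy observed compositions to RMSE
0.0096 (the noise floor for this design is about 0.01), and the
direction of the estimated interaction vector agrees with the generating
coefficients at cosine 0.89 from a single noisy realisation on the
coarse `Δt = 1` grid; on noise-free or denser data the cosine rises to
0.99–1.00.  `est.B_` itself is meaningful up to a positive constant set
by `nsum_guess`.

The same workflow from the shell:

```bash
ilvkit simulate periodic --noise 0.05 --seed 42 --out demo.tsv
ilvkit fit demo.tsv --method ilv --restarts 5 --out demo_fit.json
ilvkit evaluate demo.tsv demo_fit.json --truth demo.truth.json
ilvkit network demo_fit.json --threshold 50 --out edges.tsv
```

Datasets are plain TSV/CSV tables (first column `time`, one column per
taxon); fitted parameters are JSON.  For real datasets (e.g. lynx–hare
counts, protozoan co-cultures, a cheese microbial community), convert
counts to relative abundances (or load with `mode="absolute"` and call
`.to_composition()`), choose `--nsum-guess` by scanning a few orders of
magnitude and keeping the lowest trajectory RMSE, and use
`train_validation_protocol` for held-out evaluation.  Such tables are
not bundled; `read_timeseries` accepts any grid, including designs with
skipped days.

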