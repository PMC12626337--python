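"""Benchmarking harnesses: scenario grids, significance tests, splits.

``run_benchmark`` reproduces the simulation-study design: for each
scenario / noise / grid design point it generates replicate datasets,
fits every requested method, scores interaction recovery by off-diagonal
cosine (contrast cosine for the log-ratio method), and aggregates
mean and SD over replicates.

``compare_methods`` implements the significance protocol: a Friedman
omnibus test over paired per-replicate scores; if it rejects at 0.05, the
best-mean method is compared against each competitor by one-sided
Wilcoxon signed-rank tests, and is flagged best only when it beats all
of them at p < 0.05.  Raw p-values are reported as in the annotations of
the benchmark tables; a Holm-corrected column is emitted alongside.

``train_validation_protocol`` is the real-data evaluation design: random
train/validation splits of the time points (time 0 always trains, since
the ODE needs its anchor), fits on training residuals only, and RMSEs on
both index sets along the trajectory simulated from t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceSeries, CompositionSeries, GLVParams, simulate_relative
from .estimators import (
    fit_clv,
    fit_glv_absolute,
    fit_glv_relative,
    correlation_baseline,
    gradient_matching_regression,
)
from .ilv import ILVConfig, fit_ilv, subroutine1, subroutine2
from .metrics import cosine_clv, cosine_offdiag, trajectory_rmse
from .scenarios import Scenario, generate_dataset

__all__ = [
    "METHODS",
    "BenchmarkCell",
    "SplitResult",
    "run_benchmark",
    "compare_methods",
    "train_validation_protocol",
]

METHODS = ("ilv", "clv", "glv_relative", "pearson", "spearman", "glv_absolute")


@dataclass
class BenchmarkCell:
    method: str
    scenario: str
    dt: float
    t_range: float
    noise_level: float
    mean_cosine: float
    sd_cosine: float | None
    n_replicates: int


@dataclass
class SplitResult:
    run: int
    train_indices: np.ndarray
    val_indices: np.ndarray
    train_rmse: dict[str, float] = field(default_factory=dict)
    val_rmse: dict[str, float] = field(default_factory=dict)


def _absolute_from(series: CompositionSeries, scenario: Scenario) -> AbundanceSeries:
    """Absolute series for the absolute-data baseline: (noisy) compositions
    rescaled by the clean simulated total-abundance path."""
    traj = simulate_relative(
        scenario.params, scenario.x0, scenario.Nsum0, scenario.times
    )
    N = np.clip(series.X, 1e-6, None) * traj.Nsum[:, None]
    return AbundanceSeries(series.times, N)


def _score_method(
    method: str,
    series: CompositionSeries,
    scenario: Scenario,
    truth: GLVParams,
    ilv_config: ILVConfig,
) -> float:
    if method == "ilv":
        fit = fit_ilv(series, ilv_config)
        return cosine_offdiag(fit.params.B, truth.B)
    if method == "clv":
        return cosine_clv(fit_clv(series), truth.B)
    if method == "glv_relative":
        return cosine_offdiag(fit_glv_relative(series).B, truth.B)
    if method in ("pearson", "spearman"):
        return cosine_offdiag(correlation_baseline(series, method), truth.B)
    if method == "glv_absolute":
        abs_series = _absolute_from(series, scenario)
        params = fit_glv_absolute(abs_series, include_self=truth.self_interactions)
        return cosine_offdiag(params.B, truth.B)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_benchmark(
    scenarios: list[Scenario],
    methods: list[str] = list(METHODS),
    ilv_config: ILVConfig | None = None,
    return_replicates: bool = False,
) -> pd.DataFrame:
    """Score every (scenario, method) design point over its replicates.

    Noise-free scenarios report single-run values with no SD; noisy ones
    report the mean and SD over ``scenario.n_replicates`` seeded
    replicates.  With ``return_replicates`` the per-replicate score
    vectors are attached in a ``scores`` column (needed by
    :func:`compare_methods`).  Fully deterministic under fixed seeds.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ilv_config = ilv_config or ILVConfig()
    rows = []
    for scenario in scenarios:
        n_rep = scenario.n_replicates if scenario.noise_level > 0 else 1
        for method in methods:
            scores = []
            for rep in range(n_rep):
                series, truth = generate_dataset(scenario, rep)
                scores.append(
                    _score_method(method, series, scenario, truth, ilv_config)
                )
            scores = np.array(scores)
            cell = BenchmarkCell(
                method=method,
                scenario=scenario.name,
                dt=scenario.dt,
                t_range=scenario.t_range,
                noise_level=scenario.noise_level,
                mean_cosine=float(np.nanmean(scores)),
                sd_cosine=(
                    float(np.nanstd(scores, ddof=1))
                    if scenario.noise_level > 0 and n_rep > 1
                    else None
                ),
                n_replicates=n_rep,
            )
            row = cell.__dict__.copy()
            if return_replicates:
                row["scores"] = scores
            rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(samples: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Friedman omnibus + post-hoc one-sided Wilcoxon signed-rank.

    ``samples`` maps method names to paired score vectors of equal length.
    Returns the omnibus p-value, the best-mean method's pairwise one-sided
    p-values (raw and Holm-adjusted), and ``best`` — the method flagged
    as significantly better than every competitor, or None.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 methods")
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    n = arrays[0].shape[0]
    if n < 5 or any(a.shape[0] != n for a in arrays):
        raise ValueError("need paired samples of equal length >= 5")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        return {"friedman_p": 1.0, "best": None, "pairwise": {}, "holm": {}}
    stat, friedman_p = stats.friedmanchisquare(*arrays)
    out = {"friedman_p": float(friedman_p), "best": None, "pairwise": {}, "holm": {}}
    if friedman_p >= alpha:
        return out
    means = {nm: a.mean() for nm, a in zip(names, arrays)}
    leader = max(means, key=means.get)
    lead = np.asarray(samples[leader], dtype=float)
    pvals = {}
    for nm in names:
        if nm == leader:
            continue
        other = np.asarray(samples[nm], dtype=float)
        if np.array_equal(lead, other):
            pvals[nm] = 1.0
            continue
        pvals[nm] = float(
            stats.wilcoxon(lead, other, alternative="greater").pvalue
        )
    out["pairwise"] = {leader: pvals}
    order = sorted(pvals, key=pvals.get)
    k = len(order)
    holm, running = {}, 0.0
    for rank, nm in enumerate(order):
        running = max(running, min(1.0, (k - rank) * pvals[nm]))
        holm[nm] = running
    out["holm"] = {leader: holm}
    if pvals and all(p < alpha for p in pvals.values()):
        out["best"] = leader
    return out


def _fit_on_subset(
    method: str,
    series: CompositionSeries,
    train_idx: np.ndarray,
    ilv_config: ILVConfig,
    abs_series: AbundanceSeries | None,
):
    """Fit a trajectory-capable method using only the training time points."""
    sub = CompositionSeries(
        series.times[train_idx], series.X[train_idx], list(series.labels)
    )
    if method == "ilv":
        fit = fit_ilv(sub, ilv_config)
        return fit.params, fit.x0, fit.Nsum0
    if method == "glv_relative":
        params = fit_glv_relative(sub)
        return params, series.X[0], ilv_config.nsum_guess
    if method == "glv_absolute":
        if abs_series is None:
            raise ValueError("glv_absolute requires an absolute series")
        r, B = gradient_matching_regression(
            abs_series.N[train_idx], abs_series.times[train_idx], include_self=False
        )
        return GLVParams(r, B), series.X[0], float(abs_series.N[0].sum())
    raise ValueError(
        f"method {method!r} cannot produce trajectories "
        "(the log-ratio contrast method is excluded by construction)"
    )


def train_validation_protocol(
    series: CompositionSeries,
    n_train: int,
    runs: int,
    methods: list[str] = ["ilv", "glv_relative", "glv_absolute"],
    seed: int = 0,
    ilv_config: ILVConfig | None = None,
    abs_series: AbundanceSeries | None = None,
) -> list[SplitResult]:
    """Random train/validation splits of the time points, repeated.

    Index 0 is always assigned to training (the simulation anchor).  Each
    method is fitted on the training residuals only; the full trajectory
    is then simulated from t = 0 and RMSE evaluated separately over the
    training and held-out indices.
    """
    total = series.n_points
    if not 2 <= n_train < total:
        raise ValueError("need 2 <= n_train < number of time points")
    ilv_config = ilv_config or ILVConfig()
    results = []
    for run in range(runs):
        rng = np.random.default_rng([seed, run])
        others = rng.permutation(np.arange(1, total))
        train_idx = np.sort(np.concatenate([[0], others[: n_train - 1]]))
        val_idx = np.sort(others[n_train - 1 :])
        res = SplitResult(run=run, train_indices=train_idx, val_indices=val_idx)
        for method in methods:
            params, x0, nsum0 = _fit_on_subset(
                method, series, train_idx, ilv_config, abs_series
            )
            traj = simulate_relative(params, x0, nsum0, series.times)
            if np.isfinite(traj.X).all():
                err = series.X - traj.X
                res.train_rmse[method] = float(
                    np.sqrt(np.mean(err[train_idx] ** 2))
                )
                res.val_rmse[method] = float(np.sqrt(np.mean(err[val_idx] ** 2)))
            else:
                res.train_rmse[method] = np.inf
                res.val_rmse[method] = np.inf
        results.append(res)
    return results
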