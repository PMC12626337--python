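"""The iterative Lotka-Volterra (iLV) estimator.

iLV infers gLV growth rates and (off-diagonal) interaction coefficients
from compositional time series in two stages:

* **Iterative subroutine** (subroutine 1).  Start by pretending the total
  abundance is constant at a user-supplied guess, form pseudo-absolute
  abundances ``N = X * guess``, and fit the gradient-matching regression.
  Then alternate: simulate the relative-coordinate gLV system under the
  current parameters (initial composition = first observed row, initial
  total = the guess), rescale the observed compositions by the simulated
  total-abundance path to get refreshed pseudo-absolute abundances, and
  re-fit the regression.  Each iterate is scored by trajectory RMSE; the
  best iterate is returned as a warm start.  Because iterate 1 is the
  plain linear-approximation estimate, the selected RMSE can never exceed
  it.

* **Least-squares subroutine** (subroutine 2).  Nonlinear least squares
  on the stacked residuals (observed minus ODE-simulated relative
  abundances over all time points and species), with decision variables
  {r_i}, {b_ij, i != j} and the initial composition x(0).  The initial
  total abundance stays fixed at the guess — it is the scale gauge:
  multiplying the guess by c leaves r estimates unchanged and divides B
  by c.  Three optimizer backends are run from the same warm start (two
  Levenberg-Marquardt variants and a bounded trust-region-reflective
  variant); the untouched start is itself a candidate, and the candidate
  with the lowest trajectory RMSE wins, so the output RMSE can never
  exceed the start's.

A restart wrapper repeats subroutine 2 from multiplicatively jittered
copies of the warm start (restart 0 unjittered) and keeps the best
result.  The jitter is the controlled, seeded stand-in for the
unexplained run-to-run variability of repeated optimizer runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, leastsq
from sklearn.base import BaseEstimator

from .core import CompositionSeries, GLVParams, simulate_relative
from .estimators import gradient_matching_regression
from .metrics import trajectory_rmse

__all__ = [
    "ILVConfig",
    "FitResult",
    "subroutine1",
    "subroutine2",
    "fit_ilv",
    "optimizer_stability_report",
    "ILVRegressor",
    "BACKENDS",
]

BACKENDS = ("lm-a", "lm-b", "trf")

# residual entries where the integrator returned non-finite values are
# replaced by this flat penalty (per entry, preserving the finite part of
# the residual vector)
RESIDUAL_PENALTY = 1e3

# box used by the bounded trust-region backend
TRF_COEF_BOUND = 1.0

# residual-evaluation budget per optimizer run; generous for fits that
# converge (hundreds of evaluations) while bounding hopeless wanders
# through integration-failure plateaus
MAX_NFEV = 1000


@dataclass
class ILVConfig:
    """Tunable knobs of the iLV pipeline.

    ``nsum_guess`` is the initial guess of the total absolute abundance
    (the scale gauge for B); ``M`` the iteration budget of the iterative
    subroutine; ``restarts`` the number of jittered warm starts handed to
    the least-squares subroutine; ``jitter_sd`` the standard deviation of
    the multiplicative restart jitter.
    """

    nsum_guess: float = 200.0
    M: int = 100
    restarts: int = 20
    seed: int = 0
    backends: tuple[str, ...] = BACKENDS
    jitter_sd: float = 0.05
    early_stop_rmse: float = 1e-8

    def __post_init__(self) -> None:
        if self.nsum_guess <= 0:
            raise ValueError("nsum_guess must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        unknown = set(self.backends) - set(BACKENDS)
        if unknown:
            raise ValueError(f"unknown backends: {sorted(unknown)}")


@dataclass
class FitResult:
    """Fitted parameters plus provenance of the winning candidate."""

    params: GLVParams
    x0: np.ndarray
    Nsum0: float
    rmse: float
    backend: str
    best_iteration: int
    restart: int = 0
    rmse_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "r": self.params.r.tolist(),
            "B": self.params.B.tolist(),
            "x0": self.x0.tolist(),
            "Nsum0": self.Nsum0,
            "rmse": self.rmse,
            "backend": self.backend,
            "best_iteration": self.best_iteration,
            "restart": self.restart,
        }


def _score(series: CompositionSeries, r, B, x0, Nsum0) -> float:
    return trajectory_rmse(series, GLVParams(r, B), x0, Nsum0)


def subroutine1(
    series: CompositionSeries, config: ILVConfig
) -> tuple[GLVParams, np.ndarray, int]:
    """Iteratively refine the linear-approximation estimate.

    Returns ``(best_params, rmse_path, best_iteration)`` where iterations
    are numbered from 1 (iteration 1 = the constant-total estimate) and
    ``rmse_path[k-1]`` is the trajectory RMSE of iteration k.  The
    selected RMSE never exceeds that of iteration 1.
    """
    X = series.X
    times = series.times
    Xc = np.clip(X, 1e-6, None)
    r, B = gradient_matching_regression(Xc * config.nsum_guess, times, include_self=False)
    path = np.empty(config.M)
    best_rmse, best_params, best_iter = np.inf, None, 0
    for k in range(config.M):
        traj = simulate_relative(GLVParams(r, B), X[0], config.nsum_guess, times)
        rm = (
            float(np.sqrt(np.mean((X - traj.X) ** 2)))
            if np.isfinite(traj.X).all()
            else np.inf
        )
        path[k] = rm
        if rm < best_rmse:
            best_rmse, best_params, best_iter = rm, GLVParams(r.copy(), B.copy()), k + 1
        # refreshed pseudo-absolute abundances from the simulated total path
        Ns = traj.Nsum
        if np.isfinite(Ns).all():
            Ns = np.clip(Ns, 1e-6, 1e8)
        else:
            Ns = np.full(times.shape[0], config.nsum_guess)
        r, B = gradient_matching_regression(Xc * Ns[:, None], times, include_self=False)
    if best_params is None:
        raise RuntimeError("every iterate of the iterative subroutine was invalid")
    return best_params, path, best_iter


def _pack(r, B, x0, offmask):
    return np.concatenate([r, B[offmask], x0])


def _unpack(theta, m, offmask):
    r = theta[:m]
    B = np.zeros((m, m))
    B[offmask] = theta[m : m + m * (m - 1)]
    x0 = theta[-m:]
    return r, B, x0


def _make_residual(series: CompositionSeries, Nsum0: float, offmask):
    X, times, m = series.X, series.times, series.m

    from .core import _integrate, _rhs_rel

    def residual(theta):
        # the optimizer explores x(0) freely: no simplex projection here —
        # the raw value goes straight to the integrator, and only the
        # reported estimate is renormalized
        r, B, x0 = _unpack(theta, m, offmask)
        y, _ = _integrate(_rhs_rel, np.append(x0, Nsum0), times, (r, B))
        res = (X - y[:, :m]).ravel()
        res[~np.isfinite(res)] = RESIDUAL_PENALTY
        return res

    return residual


def subroutine2(
    series: CompositionSeries,
    start: GLVParams,
    x0_start: np.ndarray,
    Nsum0: float,
    backends: tuple[str, ...] = BACKENDS,
) -> FitResult:
    """Nonlinear least squares from a warm start, best of the backends.

    Decision variables are the growth rates, the off-diagonal interactions
    and the initial composition; the initial total abundance is held fixed
    at ``Nsum0`` (scale gauge).  The untouched start competes alongside
    the backend solutions and the lowest trajectory RMSE wins, so the
    returned RMSE never exceeds the start's.
    """
    if np.any(np.diag(start.B) != 0):
        raise ValueError("warm start must have a zero diagonal")
    m = series.m
    offmask = ~np.eye(m, dtype=bool)
    x0_start = np.asarray(x0_start, dtype=float)
    theta0 = _pack(start.r, start.B, x0_start, offmask)
    residual = _make_residual(series, Nsum0, offmask)

    candidates: list[tuple[str, np.ndarray]] = [("subroutine1-only", theta0)]
    n_coef = m + m * (m - 1)
    lo = np.concatenate([np.full(n_coef, -TRF_COEF_BOUND), np.zeros(m)])
    hi = np.concatenate([np.full(n_coef, TRF_COEF_BOUND), np.ones(m)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for backend in backends:
            try:
                if backend == "lm-a":
                    theta = leastsq(residual, theta0, maxfev=MAX_NFEV)[0]
                elif backend == "lm-b":
                    theta = least_squares(
                        residual, theta0, method="lm", max_nfev=MAX_NFEV
                    ).x
                elif backend == "trf":
                    t0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
                    theta = least_squares(
                        residual, t0, method="trf", bounds=(lo, hi),
                        max_nfev=MAX_NFEV,
                    ).x
                else:
                    raise ValueError(f"unknown backend {backend!r}")
            except ValueError:
                raise
            except Exception:
                continue  # a crashing backend only removes its candidate
            candidates.append((backend, theta))

    best = None
    for name, theta in candidates:
        r, B, x0 = _unpack(theta, m, offmask)
        rm = _score(series, r, B, x0, Nsum0)
        if best is None or rm < best[0]:
            best = (rm, name, r, B, x0)
    rm, name, r, B, x0 = best
    if not np.isfinite(rm) and name != "subroutine1-only":  # pragma: no cover
        warnings.warn("all optimizer candidates invalid; returning the start")
    x0 = np.clip(x0, 1e-6, None)
    x0 = x0 / x0.sum()
    return FitResult(
        params=GLVParams(r, B),
        x0=x0,
        Nsum0=Nsum0,
        rmse=rm,
        backend=name,
        best_iteration=0,
    )


def fit_ilv(series: CompositionSeries, config: ILVConfig | None = None) -> FitResult:
    """Full iLV pipeline: iterative warm start, restarts, best of backends.

    Restart 0 hands the iterative subroutine's best iterate straight to
    the least-squares subroutine; restarts 1..R-1 first multiply the warm
    start elementwise by (1 + delta), delta ~ N(0, jitter_sd), with
    per-restart seeds derived from ``config.seed``.  The minimum-RMSE
    result over restarts is returned (ties favor the earliest restart);
    everything is deterministic given the config.
    """
    config = config or ILVConfig()
    start, path, best_iter = subroutine1(series, config)
    x0_obs = series.X[0]
    best: FitResult | None = None
    for restart in range(config.restarts):
        if restart == 0:
            r, B = start.r, start.B
        else:
            rng = np.random.default_rng([config.seed, restart])
            jr = 1.0 + rng.normal(0.0, config.jitter_sd, size=start.r.shape)
            jB = 1.0 + rng.normal(0.0, config.jitter_sd, size=start.B.shape)
            r = start.r * jr
            B = start.B * jB
            np.fill_diagonal(B, 0.0)
        fit = subroutine2(
            series, GLVParams(r, B), x0_obs, config.nsum_guess, config.backends
        )
        fit.restart = restart
        if best is None or fit.rmse < best.rmse:
            best = fit
        if best.rmse < config.early_stop_rmse:
            # below the integration tolerance the residuals are solver noise;
            # further jittered restarts cannot improve the fit
            break
    best.best_iteration = best_iter
    best.rmse_path = path
    return best


def optimizer_stability_report(
    series: CompositionSeries, config: ILVConfig, runs: int
):
    """Re-run the pipeline per backend with distinct restart seeds.

    Returns a pandas DataFrame with one row per backend (min / mean /
    median / max trajectory RMSE over ``runs`` repetitions), mirroring
    the repeated-run instability comparison of the three optimizers.
    """
    import pandas as pd

    if runs < 2:
        raise ValueError("need at least 2 runs")
    rows = []
    for backend in config.backends:
        rmses = []
        for run in range(runs):
            cfg = ILVConfig(
                nsum_guess=config.nsum_guess,
                M=config.M,
                restarts=config.restarts,
                seed=int(np.random.default_rng([config.seed, run]).integers(2**31)),
                backends=(backend,),
                jitter_sd=config.jitter_sd,
            )
            rmses.append(fit_ilv(series, cfg).rmse)
        rmses = np.asarray(rmses)
        rows.append(
            {
                "backend": backend,
                "min": rmses.min(),
                "mean": rmses.mean(),
                "median": float(np.median(rmses)),
                "max": rmses.max(),
                "runs": runs,
            }
        )
    return pd.DataFrame(rows).set_index("backend")


class ILVRegressor(BaseEstimator):
    """iLV as a scikit-learn estimator.

    Parameters mirror :class:`ILVConfig`; ``fit(X, times)`` takes the
    (n+1, m) relative-abundance matrix and its sampling times, and
    ``predict(times)`` simulates the fitted system on an arbitrary grid.

    Attributes
    ----------
    r_, B_ : fitted growth rates and interaction matrix (zero diagonal;
        B is identified only up to the positive gauge constant set by
        ``nsum_guess``).
    x0_ : fitted initial composition (on the simplex).
    rmse_ : trajectory RMSE of the winning candidate.
    backend_, restart_, best_iteration_, rmse_path_ : provenance of the
        winning candidate and the iterative subroutine's RMSE sequence.
    """

    def __init__(
        self,
        nsum_guess: float = 200.0,
        M: int = 100,
        restarts: int = 20,
        backends: tuple[str, ...] = BACKENDS,
        jitter_sd: float = 0.05,
        random_state: int = 0,
    ):
        self.nsum_guess = nsum_guess
        self.M = M
        self.restarts = restarts
        self.backends = backends
        self.jitter_sd = jitter_sd
        self.random_state = random_state

    def _config(self) -> ILVConfig:
        return ILVConfig(
            nsum_guess=self.nsum_guess,
            M=self.M,
            restarts=self.restarts,
            seed=self.random_state,
            backends=tuple(self.backends),
            jitter_sd=self.jitter_sd,
        )

    def fit(self, X, times):
        series = (
            X
            if isinstance(X, CompositionSeries)
            else CompositionSeries(np.asarray(times, float), np.asarray(X, float))
        )
        result = fit_ilv(series, self._config())
        self.result_ = result
        self.r_ = result.params.r
        self.B_ = result.params.B
        self.x0_ = result.x0
        self.nsum0_ = result.Nsum0
        self.rmse_ = result.rmse
        self.backend_ = result.backend
        self.restart_ = result.restart
        self.best_iteration_ = result.best_iteration
        self.rmse_path_ = result.rmse_path
        self.n_features_in_ = series.m
        return self

    def predict(self, times) -> np.ndarray:
        """Simulated relative abundances of the fitted system."""
        traj = simulate_relative(
            self.result_.params, self.x0_, self.nsum0_, np.asarray(times, float)
        )
        return traj.X

    def score(self, X, times) -> float:
        """Negative trajectory RMSE (larger is better)."""
        series = (
            X
            if isinstance(X, CompositionSeries)
            else CompositionSeries(np.asarray(times, float), np.asarray(X, float))
        )
        return -trajectory_rmse(series, self.result_.params, self.x0_, self.nsum0_)
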