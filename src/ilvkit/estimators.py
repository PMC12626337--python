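"""Gradient-matching (linear-approximation) estimators and baselines.

The workhorse identity is the log-derivative form of the gLV model,

    d(ln N_i)/dt = r_i + sum_j b_ij N_j,

whose left side is approximated by forward finite differences
``(ln N_i(t_{k+1}) - ln N_i(t_k)) / (t_{k+1} - t_k)``.  Parameter
estimation then reduces to one ordinary least-squares regression per
species: intercept = r_i, slopes = b_ij.  Applied to absolute abundances
this is the classical gLV regression (``gLV_absolute``); applied verbatim
to relative abundances it is the ``gLV_relative`` baseline, for which the
diagonal b_ii is unidentifiable (substituting the simplex constraint into
the regression leaves only r_i + b_i1 and b_ij - b_i1 determined) and is
therefore pinned to zero.

Also provided: a log-ratio contrast regression standing in for the
compositional LV (cLV) approach — it estimates the contrast directions
``r_i - r_D`` and ``b_ij - b_Dj`` against a minimum-variance reference
species D — and Pearson/Spearman correlation matrices used as naive
interaction proxies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import AbundanceSeries, CompositionSeries, GLVParams

__all__ = [
    "log_gradient",
    "gradient_matching_regression",
    "GLVGradientRegressor",
    "CLVContrastRegressor",
    "CorrelationInteractions",
    "CLVResult",
    "fit_glv_absolute",
    "fit_glv_relative",
    "fit_clv",
    "correlation_baseline",
]

CLIP_FLOOR = 1e-6


def log_gradient(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Per-interval forward log-gradients (ln v_{k+1} - ln v_k) / Δt_k.

    Supports non-uniform grids.  Raises on non-positive values, naming the
    offending index; callers working with compositions clip at 1e-6 first.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape[0] != times.shape[0] or values.shape[0] < 2:
        raise ValueError("values and times must share a length >= 2")
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(f"non-positive value at index {bad[0]}")
    return np.diff(np.log(values)) / np.diff(times)


def _design_values(V: np.ndarray, timing: str) -> np.ndarray:
    if timing == "left":
        return V[:-1]
    if timing == "midpoint":
        return 0.5 * (V[:-1] + V[1:])
    raise ValueError(f"unknown regressor timing {timing!r}")


def gradient_matching_regression(
    V: np.ndarray,
    times: np.ndarray,
    include_self: bool,
    timing: str = "left",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species OLS of log-gradients on (left-endpoint) abundances.

    Returns ``(r_hat, B_hat)``.  When ``include_self`` is False the
    regression for species i omits column i and ``B_hat[i, i] = 0``.
    Singular designs fall back to the minimum-norm least-squares solution
    with a rank warning.
    """
    V = np.asarray(V, dtype=float)
    times = np.asarray(times, dtype=float)
    n1, m = V.shape
    n_coef = m if include_self else m - 1
    if n1 - 1 < n_coef + 1:
        warnings.warn(
            f"only {n1 - 1} intervals for {n_coef + 1} coefficients; "
            "design is rank-deficient",
            stacklevel=2,
        )
    regressors = _design_values(V, timing)
    r_hat = np.zeros(m)
    B_hat = np.zeros((m, m))
    for i in range(m):
        y = log_gradient(V[:, i], times)
        cols = [j for j in range(m) if include_self or j != i]
        A = np.column_stack([np.ones(y.shape[0]), regressors[:, cols]])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            warnings.warn(
                f"rank-deficient design for species {i}; "
                "minimum-norm solution returned",
                stacklevel=2,
            )
        r_hat[i] = beta[0]
        B_hat[i, cols] = beta[1:]
    return r_hat, B_hat


class GLVGradientRegressor(BaseEstimator):
    """Gradient-matching gLV regression as a scikit-learn estimator.

    Fits one OLS regression per species of the forward log-gradient on
    species abundances evaluated at the left endpoint of each interval
    (``timing='midpoint'`` averages the two endpoints instead).  Works on
    absolute abundances (self-interaction columns optional) or, applied
    directly to compositions with ``include_self=False``, reproduces the
    gLV_relative baseline.

    Parameters
    ----------
    include_self : bool, default False
        Whether the diagonal b_ii is estimated.  Must be False for
        relative-abundance input, where the diagonal is unidentifiable.
    timing : {'left', 'midpoint'}, default 'left'
        Where the regressor abundances are evaluated on each interval.
    clip_floor : float, default 1e-6
        Values are clipped below at this floor before the log transform.

    Attributes
    ----------
    r_ : (m,) ndarray of fitted growth rates.
    B_ : (m, m) ndarray of fitted interactions.
    params_ : GLVParams bundling the two.
    """

    def __init__(
        self,
        include_self: bool = False,
        timing: str = "left",
        clip_floor: float = CLIP_FLOOR,
    ):
        self.include_self = include_self
        self.timing = timing
        self.clip_floor = clip_floor

    def fit(self, X, times):
        V = np.clip(np.asarray(X, dtype=float), self.clip_floor, None)
        self.r_, self.B_ = gradient_matching_regression(
            V, times, include_self=self.include_self, timing=self.timing
        )
        self.params_ = GLVParams(self.r_, self.B_, self.include_self)
        self.n_features_in_ = V.shape[1]
        return self


@dataclass
class CLVResult:
    """Identifiable contrasts of the log-ratio (cLV-style) regression.

    ``D`` is the reference species (lowest sample variance of relative
    abundance, ties broken toward the lowest index).  ``r_diff[i]``
    estimates (a scaled contrast involving) r_i - r_D; ``B_diff[i, j]``
    the direction of b_ij - b_Dj, for i != D and j != D.  Excluded rows
    and columns are NaN.  Only contrast directions are meaningful.
    """

    D: int
    r_diff: np.ndarray
    B_diff: np.ndarray


class CLVContrastRegressor(BaseEstimator):
    """Additive-log-ratio gradient regression against a reference species.

    For each species i != D, regresses the forward log-gradient of
    x_i / x_D on the left-endpoint relative abundances {x_j, j != D} with
    intercept.  Slopes estimate scaled contrasts b_ij - b_Dj, the
    intercept r_i - r_D.  Absolute coefficient values are not recoverable
    from compositions; this estimator is scored through contrast cosines
    only.
    """

    def __init__(self, timing: str = "left", clip_floor: float = CLIP_FLOOR):
        self.timing = timing
        self.clip_floor = clip_floor

    def fit(self, X, times):
        X = np.clip(np.asarray(X, dtype=float), self.clip_floor, None)
        times = np.asarray(times, dtype=float)
        n1, m = X.shape
        if m < 2:
            raise ValueError("need at least 2 species")
        variances = X.var(axis=0)
        D = int(np.argmin(variances))  # argmin takes the lowest index on ties
        others = [j for j in range(m) if j != D]
        regressors = _design_values(X, self.timing)[:, others]
        A = np.column_stack([np.ones(n1 - 1), regressors])
        rank = np.linalg.matrix_rank(A)
        if rank < 2:
            # nothing beyond the intercept: constant compositions carry no
            # gradient information at all
            raise ValueError(
                "log-ratio design is rank deficient "
                "(constant composition cannot be regressed)"
            )
        if rank < A.shape[1]:
            warnings.warn(
                "collinear log-ratio design; minimum-norm solution returned",
                stacklevel=2,
            )
        r_diff = np.full(m, np.nan)
        B_diff = np.full((m, m), np.nan)
        for i in others:
            y = log_gradient(X[:, i] / X[:, D], times)
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            r_diff[i] = beta[0]
            B_diff[i, others] = beta[1:]
        self.D_ = D
        self.r_diff_ = r_diff
        self.B_diff_ = B_diff
        self.result_ = CLVResult(D, r_diff, B_diff)
        self.n_features_in_ = m
        return self


class CorrelationInteractions(BaseEstimator):
    """Pairwise correlation of relative-abundance series as a naive proxy
    for interaction coefficients.

    Entry (i, j) is the Pearson or Spearman correlation between the two
    species' time series; the diagonal is set to 0 so the matrix can be
    scored through the off-diagonal cosine like a fitted B.  Zero-variance
    series yield 0 with a warning.
    """

    def __init__(self, method: str = "pearson"):
        self.method = method

    def fit(self, X, times=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if self.method == "pearson":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                C = np.corrcoef(X, rowvar=False)
        elif self.method == "spearman":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                C = stats.spearmanr(X).statistic
                C = np.atleast_2d(C)
                if C.shape == (1, 1):  # m == 2 returns a scalar
                    rho = float(C[0, 0])
                    C = np.array([[1.0, rho], [rho, 1.0]])
        else:
            raise ValueError(f"unknown correlation method {self.method!r}")
        if np.isnan(C).any():
            warnings.warn(
                "zero-variance series; correlations set to 0", stacklevel=2
            )
            C = np.nan_to_num(C)
        np.fill_diagonal(C, 0.0)
        self.matrix_ = C
        self.n_features_in_ = X.shape[1]
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator classes


def fit_glv_absolute(
    series: AbundanceSeries, include_self: bool = False, timing: str = "left"
) -> GLVParams:
    """gLV_absolute baseline: gradient-matching regression on absolute data."""
    est = GLVGradientRegressor(include_self=include_self, timing=timing)
    return est.fit(series.N, series.times).params_


def fit_glv_relative(series: CompositionSeries, timing: str = "left") -> GLVParams:
    """gLV_relative baseline: the same regression applied directly to
    compositions, self columns always excluded."""
    est = GLVGradientRegressor(include_self=False, timing=timing)
    return est.fit(series.X, series.times).params_


def fit_clv(series: CompositionSeries, timing: str = "left") -> CLVResult:
    """Log-ratio contrast regression (cLV surrogate)."""
    est = CLVContrastRegressor(timing=timing)
    return est.fit(series.X, series.times).result_


def correlation_baseline(
    series: CompositionSeries, method: str = "pearson"
) -> np.ndarray:
    """Correlation-matrix baseline with zeroed diagonal."""
    return CorrelationInteractions(method=method).fit(series.X).matrix_
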