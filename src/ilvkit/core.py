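"""Generalized Lotka-Volterra dynamics in absolute and relative coordinates.

The gLV system for m interacting populations with absolute abundances
``N_1 .. N_m`` is

    dN_i/dt = r_i N_i + sum_j b_ij N_i N_j

where ``r_i`` is the per-capita growth rate of species i and ``b_ij`` the
per-capita effect of species j on species i.  Writing ``N_sum = sum_i N_i``
and relative abundances ``x_i = N_i / N_sum``, the same dynamics become a
closed system in ``(x_1 .. x_m, N_sum)``:

    dN_sum/dt = sum_i ( r_i x_i N_sum + sum_j b_ij x_i x_j N_sum^2 )
    dx_i/dt   = ( r_i x_i N_sum + sum_j b_ij x_i x_j N_sum^2
                  - x_i dN_sum/dt ) / N_sum

The relative form is what a compositional (sequencing-style) observation
process sees, up to the latent total ``N_sum``.  By construction
``sum_i dx_i/dt = 0``, so simplex trajectories stay on the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "GLVParams",
    "CompositionSeries",
    "AbundanceSeries",
    "Trajectory",
    "relative_rhs",
    "simulate_relative",
    "simulate_absolute",
]

#: absolute total-abundance magnitude beyond which a trajectory is flagged
#: as blown up (diagnostic only; compositional fits remain scoreable as long
#: as the compositions themselves are finite)
NSUM_BLOWUP = 1e8

#: integration tolerances (rtol = atol)
ODE_TOL = 1e-8

#: cap on internal integrator steps per output interval (the library
#: solver's default; failed candidate fits abort quickly at this cap)
ODE_MXSTEP = 500


@dataclass
class GLVParams:
    """Growth rates and interaction matrix of a gLV system.

    Parameters
    ----------
    r : (m,) array
        Per-capita growth rates, units 1/time.
    B : (m, m) array
        Interaction matrix; ``B[i, j]`` is the effect of species j on
        species i, units 1/(abundance * time).
    self_interactions : bool
        Whether diagonal entries are free.  When False every ``b_ii`` must
        be exactly zero (the convention for all relative-input methods,
        where the diagonal is unidentifiable).
    """

    r: np.ndarray
    B: np.ndarray
    self_interactions: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        m = self.r.shape[0]
        if self.B.shape != (m, m):
            raise ValueError(f"B must be {(m, m)}, got {self.B.shape}")
        if not (np.isfinite(self.r).all() and np.isfinite(self.B).all()):
            raise ValueError("gLV parameters must be finite")
        if not self.self_interactions and np.any(np.diag(self.B) != 0.0):
            raise ValueError(
                "diagonal of B must be exactly 0 when self_interactions=False"
            )

    @property
    def m(self) -> int:
        return self.r.shape[0]

    def copy(self) -> "GLVParams":
        return GLVParams(self.r.copy(), self.B.copy(), self.self_interactions)


def _check_times(times: np.ndarray, min_len: int = 2) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.shape[0] < min_len:
        raise ValueError(f"times must be 1-D with at least {min_len} points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


@dataclass
class CompositionSeries:
    """Observed relative abundances on a (possibly non-uniform) time grid.

    Rows of ``X`` live on the probability simplex: entries in [0, 1] and
    each row sums to 1 (within 1e-8 after ingest normalization).
    """

    times: np.ndarray
    X: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        self.X = np.asarray(self.X, dtype=float)
        n1 = self.times.shape[0]
        if self.X.ndim != 2 or self.X.shape[0] != n1:
            raise ValueError("X must have one row per time point")
        if self.X.shape[1] < 2:
            raise ValueError("need at least 2 species")
        if np.any(self.X < 0) or np.any(self.X > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        if np.max(np.abs(self.X.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("rows of X must sum to 1 (tolerance 1e-8)")
        if not self.labels:
            self.labels = [f"sp{i + 1}" for i in range(self.X.shape[1])]
        if len(self.labels) != self.X.shape[1]:
            raise ValueError("one label per species required")

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n_points(self) -> int:
        return self.times.shape[0]


@dataclass
class AbundanceSeries:
    """Strictly positive absolute abundances on a time grid."""

    times: np.ndarray
    N: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        self.N = np.asarray(self.N, dtype=float)
        if self.N.ndim != 2 or self.N.shape[0] != self.times.shape[0]:
            raise ValueError("N must have one row per time point")
        if np.any(self.N <= 0) or not np.isfinite(self.N).all():
            raise ValueError("absolute abundances must be strictly positive")
        if not self.labels:
            self.labels = [f"sp{i + 1}" for i in range(self.N.shape[1])]

    @property
    def m(self) -> int:
        return self.N.shape[1]

    def to_composition(self) -> CompositionSeries:
        """Convert to relative abundances x_i = N_i / N_sum."""
        X = self.N / self.N.sum(axis=1, keepdims=True)
        X = X / X.sum(axis=1, keepdims=True)
        return CompositionSeries(self.times, X, list(self.labels))


@dataclass
class Trajectory:
    """Simulated relative abundances plus the latent total-abundance path.

    ``X`` holds the reported (row-renormalized) compositions, ``X_raw`` the
    solver states before renormalization.  ``valid`` is False when the
    integrator failed or produced non-finite values; ``blowup`` flags
    |N_sum| exceeding 1e8 (a diagnostic: the compositional path may still
    be perfectly well-behaved when the total overflows).
    """

    times: np.ndarray
    X: np.ndarray
    Nsum: np.ndarray
    valid: bool
    X_raw: np.ndarray | None = None
    blowup: bool = False


def relative_rhs(
    x: np.ndarray, Nsum: float, params: GLVParams
) -> tuple[np.ndarray, float]:
    """Right-hand side of the relative-coordinate gLV system.

    Returns ``(dx/dt, dNsum/dt)`` evaluated at state ``(x, Nsum)``.  The
    components of dx/dt sum to zero analytically.
    """
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(Nsum)):
        raise ValueError("non-finite state passed to relative_rhs")
    if np.any(x < -1e-6) or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("x must lie on the simplex (tolerance 1e-6)")
    if Nsum <= 0:
        raise ValueError("Nsum must be positive")
    growth = x * (params.r + (params.B @ x) * Nsum) * Nsum  # dN_i/dt
    dNsum = growth.sum()
    dx = (growth - x * dNsum) / Nsum
    return dx, dNsum


def _rhs_rel(y: np.ndarray, t: float, r: np.ndarray, B: np.ndarray) -> np.ndarray:
    # odeint callback; no validation on the hot path
    m = r.shape[0]
    x, Ns = y[:m], y[m]
    growth = x * (r + (B @ x) * Ns) * Ns
    dNs = growth.sum()
    out = np.empty(m + 1)
    out[:m] = (growth - x * dNs) / Ns if Ns != 0 else 0.0
    out[m] = dNs
    return out


def _rhs_abs(N: np.ndarray, t: float, r: np.ndarray, B: np.ndarray) -> np.ndarray:
    return N * (r + B @ N)


def _integrate(rhs, y0, times, args):
    """odeint wrapper: silence warnings, never raise on blow-up.

    When LSODA aborts mid-way, the rows of its output array beyond the
    failure point are uninitialized memory; those rows are overwritten
    with NaN (detected via the per-output integration times in
    ``infodict['tcur']``) so that failures are deterministic and
    downstream penalty handling sees an explicit non-finite marker.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            y, info = odeint(
                rhs,
                y0,
                times,
                args=args,
                rtol=ODE_TOL,
                atol=ODE_TOL,
                mxstep=ODE_MXSTEP,
                full_output=True,
            )
        except Exception:  # pragma: no cover - defensive
            return np.full((len(times), len(y0)), np.nan), False
    success = info["message"] == "Integration successful."
    if not success:
        tcur = info["tcur"]
        eps = 1e-9
        valid_rows = 1  # the initial condition is always valid
        prev = times[0]
        for k in range(len(times) - 1):
            reached = tcur[k] if k < len(tcur) else np.nan
            target = times[k + 1]
            if (
                not np.isfinite(reached)
                or reached < prev
                or reached < target - eps * max(1.0, abs(target))
            ):
                break
            prev = reached
            valid_rows = k + 2
        y[valid_rows:] = np.nan
    return y, success


def simulate_relative(
    params: GLVParams,
    x0: np.ndarray,
    Nsum0: float,
    times: np.ndarray,
) -> Trajectory:
    """Integrate the relative-coordinate system on the requested grid.

    Reported rows are renormalized to the simplex; raw solver states are
    kept in ``X_raw``.  Integration blow-up yields ``valid=False`` rather
    than an exception so candidate-scoring loops can continue.
    """
    x0 = np.asarray(x0, dtype=float)
    times = _check_times(times)
    if not np.isfinite(x0).all() or abs(x0.sum() - 1.0) > 1e-6 or np.any(x0 < -1e-6):
        raise ValueError("x0 must lie on the simplex")
    if not (np.isfinite(Nsum0) and Nsum0 > 0):
        raise ValueError("Nsum0 must be positive")
    y, success = _integrate(
        _rhs_rel, np.append(x0, Nsum0), times, (params.r, params.B)
    )
    X_raw, Nsum = y[:, :-1], y[:, -1]
    finite = bool(np.isfinite(y).all())
    valid = finite and success
    blowup = (not finite) or bool(np.max(np.abs(Nsum)) > NSUM_BLOWUP)
    X = X_raw.copy()
    if finite:
        sums = X.sum(axis=1, keepdims=True)
        good = (sums > 0).ravel()
        X[good] = X[good] / sums[good]
    return Trajectory(times, X, Nsum, valid, X_raw=X_raw, blowup=blowup)


def simulate_absolute(
    params: GLVParams,
    N0: np.ndarray,
    times: np.ndarray,
) -> AbundanceSeries | None:
    """Integrate the absolute-coordinate system dN_i/dt = N_i (r_i + Σ b_ij N_j).

    Returns None when the solve blows up (non-finite or non-positive states),
    mirroring the validity contract of :func:`simulate_relative`.
    """
    N0 = np.asarray(N0, dtype=float)
    times = _check_times(times)
    if np.any(N0 <= 0) or not np.isfinite(N0).all():
        raise ValueError("N0 must be strictly positive")
    y, success = _integrate(_rhs_abs, N0, times, (params.r, params.B))
    if not (success and np.isfinite(y).all() and np.all(y > 0)):
        return None
    return AbundanceSeries(times, y)
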