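"""Scoring: trajectory RMSE, off-diagonal cosine similarity, network rule.

Trajectory RMSE compares observed and model-simulated relative abundances
over every sampled time point and species:

    RMSE = sqrt( sum_{k=0}^{n} sum_{j=1}^{m} g_j(t_k)^2 / ((n+1) m) ),
    g_j(t_k) = x_j^obs(t_k) - x_j^sim(t_k).

The k = 0 term is included: once the initial composition itself is
optimized it generally carries a nonzero residual.

Interaction recovery is scored through the cosine of the angle between
the concatenated off-diagonal entries of the estimated and true
interaction matrices.  Because compositions identify b_ij only up to a
positive constant (the total-abundance gauge), the cosine — invariant
under positive rescaling — is the natural recovery metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CompositionSeries, GLVParams, simulate_relative
from .estimators import CLVResult

__all__ = [
    "trajectory_rmse",
    "cosine_offdiag",
    "cosine_clv",
    "extract_network",
    "InteractionNetwork",
]


def trajectory_rmse(
    observed: CompositionSeries,
    params: GLVParams,
    x0: np.ndarray,
    Nsum0: float,
) -> float:
    """RMSE between observations and the model trajectory on the same grid.

    The initial composition is clipped to the open simplex and
    renormalized before simulation.  Returns +inf when the simulated
    compositions are non-finite.  A finite composition path whose total
    abundance overflows is still scored: the compositional fit is defined
    regardless of the (unidentifiable) total's magnitude.
    """
    x0 = np.clip(np.asarray(x0, dtype=float), 1e-6, None)
    x0 = x0 / x0.sum()
    traj = simulate_relative(params, x0, Nsum0, observed.times)
    if not np.isfinite(traj.X).all():
        return np.inf
    return float(np.sqrt(np.mean((observed.X - traj.X) ** 2)))


def _offdiag(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    mask = ~np.eye(M.shape[0], dtype=bool)
    return M[mask]  # row-major concatenation of off-diagonal entries


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine undefined for a zero vector", stacklevel=3)
        return float("nan")
    return float(a @ b / (na * nb))


def cosine_offdiag(B_hat: np.ndarray, B_true: np.ndarray) -> float:
    """Cosine similarity of concatenated off-diagonal interaction entries.

    The diagonal never enters; positive rescaling of either argument
    leaves the value unchanged (the property that makes the b_ij scale
    gauge harmless).  NaN with a warning when either off-diagonal vector
    is zero.
    """
    B_hat = np.asarray(B_hat, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    if B_hat.shape != B_true.shape or B_hat.shape[0] < 2:
        raise ValueError("matrices must share a shape with m >= 2")
    return _cosine(_offdiag(B_hat), _offdiag(B_true))


def cosine_clv(
    contrasts_hat: CLVResult, B_true: np.ndarray, r_true: np.ndarray | None = None
) -> float:
    """Cosine between estimated and true contrast vectors b_ij - b_Dj.

    The true contrasts are built over exactly the index set the estimate
    covers (i != D, j != D, i != j, with the estimate's reference species
    D), then compared by plain cosine.
    """
    B_true = np.asarray(B_true, dtype=float)
    D = contrasts_hat.D
    m = B_true.shape[0]
    if contrasts_hat.B_diff.shape != (m, m):
        raise ValueError("contrast estimate and truth have mismatched sizes")
    est, truth = [], []
    for i in range(m):
        for j in range(m):
            if i == D or j == D or i == j:
                continue
            if np.isnan(contrasts_hat.B_diff[i, j]):
                raise ValueError(f"estimate missing contrast ({i}, {j})")
            est.append(contrasts_hat.B_diff[i, j])
            truth.append(B_true[i, j] - B_true[D, j])
    return _cosine(np.asarray(est), np.asarray(truth))


@dataclass
class InteractionNetwork:
    """Thresholded directed interaction network.

    Edges are (source j, target i, |b_ij|, sign) tuples where sign is
    "promotion" for b_ij > 0 and "inhibition" for b_ij < 0.  Retained
    edges satisfy |b_ij| >= threshold_factor * min off-diagonal |b_ij|
    (minimum over nonzero entries); self-edges are never included.
    """

    edges: list[tuple[int, int, float, str]] = field(default_factory=list)
    threshold_factor: float = 50.0
    labels: list[str] = field(default_factory=list)

    def to_networkx(self):
        """Directed graph with weight/sign edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        names = self.labels or None
        for src, tgt, w, sign in self.edges:
            u = names[src] if names else src
            v = names[tgt] if names else tgt
            g.add_edge(u, v, weight=w, sign=sign)
        return g


def extract_network(
    params: GLVParams,
    threshold_factor: float = 50.0,
    labels: list[str] | None = None,
) -> InteractionNetwork:
    """Keep off-diagonal interactions at least ``threshold_factor`` times
    the smallest nonzero off-diagonal magnitude.

    With the default factor of 50 only clearly dominant interactions
    survive; factor 1 keeps every nonzero off-diagonal edge.
    """
    B = params.B
    m = B.shape[0]
    if m < 2:
        raise ValueError("need at least 2 species")
    off = np.abs(_offdiag(B))
    nonzero = off[off > 0]
    net = InteractionNetwork(
        threshold_factor=threshold_factor, labels=list(labels or [])
    )
    if nonzero.size == 0:
        warnings.warn("all off-diagonal interactions are zero", stacklevel=2)
        return net
    cutoff = threshold_factor * nonzero.min()
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            w = abs(B[i, j])
            if w > 0 and w >= cutoff:
                sign = "promotion" if B[i, j] > 0 else "inhibition"
                net.edges.append((j, i, w, sign))
    return net
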