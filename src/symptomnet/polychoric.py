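"""Association matrices for ordinal data: two-step polychoric ML with fallbacks.

The polychoric model treats each ordinal variable as a discretized latent
standard-normal variable: K observed categories correspond to K-1 strictly
increasing cut-points (thresholds).  Estimation is two-step — thresholds are
fixed at their marginal inverse-normal estimates, then the latent correlation
rho maximizes the bivariate-normal contingency-table likelihood in a 1-D
bounded search.

Variables with many observed categories (scale totals, continuous scores)
are numerically awkward for polychoric estimation, so the pairwise method is
chosen by a policy: polychoric when both variables have few categories,
Pearson when both look continuous, Spearman otherwise.  The resulting matrix
is repaired to the nearest correlation matrix when indefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri, owens_t
from statsmodels.stats.correlation_tools import corr_nearest

from .scales import LikertResponseTable, ScaleScoreTable

__all__ = [
    "CorrelationMatrix",
    "CorrelationPolicy",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric_pair",
    "build_correlation_matrix",
]

_RHO_BOUND = 0.999
_CELL_FLOOR = 1e-12


class DegenerateVariableError(ValueError):
    """A variable has fewer than two observed categories."""


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Vectorized over ``h``/``k`` (broadcast to a common shape); infinite
    bounds are handled exactly.  Uses Owen's T function; absolute accuracy
    is ~1e-14 in the interior.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)

    if rho >= 1.0 - 1e-12:
        out[...] = ndtr(np.minimum(h, k))
        return out
    if rho <= -1.0 + 1e-12:
        out[...] = np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)
        return out

    # Infinite bounds reduce to univariate margins.
    out[...] = np.nan
    hi_h, hi_k = np.isposinf(h), np.isposinf(k)
    lo = np.isneginf(h) | np.isneginf(k)
    out[lo] = 0.0
    both_fin = ~(hi_h | hi_k | lo)
    out[hi_h & ~lo & ~hi_k] = ndtr(k[hi_h & ~lo & ~hi_k])
    out[hi_k & ~lo & ~hi_h] = ndtr(h[hi_k & ~lo & ~hi_h])
    out[hi_h & hi_k] = 1.0

    if both_fin.any():
        # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - delta.
        # Exact zeros are nudged off the removable singularity at h=0.
        hf = np.where(h[both_fin] == 0.0, 1e-13, h[both_fin])
        kf = np.where(k[both_fin] == 0.0, 1e-13, k[both_fin])
        s = np.sqrt(1.0 - rho * rho)
        a_h = (kf - rho * hf) / (hf * s)
        a_k = (hf - rho * kf) / (kf * s)
        delta = np.where(hf * kf > 0, 0.0, 0.5)
        val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - delta
        out[both_fin] = np.clip(val, 0.0, 1.0)
    return out


def estimate_thresholds(x) -> np.ndarray:
    """Marginal thresholds: tau_k = Phi^-1(cumulative proportion <= category k).

    Returns the K-1 interior cut-points for the K observed categories of the
    ordinal vector ``x`` (missing values dropped).  Raises
    :class:`DegenerateVariableError` for single-category input.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise DegenerateVariableError("empty vector")
    cats, counts = np.unique(x, return_counts=True)
    if cats.size < 2:
        raise DegenerateVariableError("degenerate variable: single observed category")
    cum = np.cumsum(counts[:-1]) / x.size
    return ndtri(cum)


def _cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ay = np.concatenate(([-np.inf], tau_y, [np.inf]))
    grid = bvn_cdf(ax[:, None], ay[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def polychoric_pair(x, y, return_details: bool = False):
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds are fixed at their marginal estimates; rho is found by a
    bounded scalar likelihood search on [-0.999, 0.999].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError("need at least 10 complete pairs")
    tau_x = estimate_thresholds(x)
    tau_y = estimate_thresholds(y)
    cats_x = np.unique(x)
    cats_y = np.unique(y)
    table = np.zeros((cats_x.size, cats_y.size))
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    np.add.at(table, (ix, iy), 1.0)

    def negll(rho: float) -> float:
        probs = np.maximum(_cell_probabilities(tau_x, tau_y, rho), _CELL_FLOOR)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"polychoric optimizer failed to converge: {res.message}")
    rho = float(res.x)
    if return_details:
        return rho, {"thresholds_x": tau_x, "thresholds_y": tau_y, "negll": float(res.fun)}
    return rho


@dataclass
class CorrelationPolicy:
    """Chooses the pairwise association method.

    Polychoric is used when both variables are integer-coded with at most
    ``max_categories`` observed levels; Pearson when both are continuous;
    Spearman rank correlation otherwise.  ``bin_deciles=True`` instead bins
    every many-category variable into (at most) deciles so polychoric can be
    used throughout.
    """

    max_categories: int = 10
    bin_deciles: bool = False
    psd_tol: float = 1e-8


@dataclass
class CorrelationMatrix:
    """p x p symmetric unit-diagonal association matrix."""

    values: np.ndarray
    node_names: list[str]
    method_per_pair: dict[tuple[str, str], str] = field(default_factory=dict)
    psd_repaired: bool = False
    n: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.node_names, columns=self.node_names).to_csv(path)


def _classify(col: np.ndarray, max_categories: int) -> str:
    vals = col[~np.isnan(col)]
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise DegenerateVariableError("degenerate variable in correlation input")
    if np.allclose(uniq, np.round(uniq)):
        return "ordinal" if uniq.size <= max_categories else "many"
    return "continuous"


def _decile_bin(col: np.ndarray) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, 11)[1:-1])
    return np.searchsorted(np.unique(qs), col, side="left").astype(float)


def build_correlation_matrix(
    data: ScaleScoreTable | LikertResponseTable | pd.DataFrame,
    policy: CorrelationPolicy | None = None,
) -> CorrelationMatrix:
    """Pairwise association matrix over the columns of *data*.

    Rows with any missing value are dropped (listwise).  Requires n > p.
    The matrix is projected to the nearest correlation matrix when its
    smallest eigenvalue is below ``-policy.psd_tol``; ``psd_repaired``
    records whether that happened.
    """
    policy = policy or CorrelationPolicy()
    if isinstance(data, ScaleScoreTable):
        df = data.scores
    elif isinstance(data, LikertResponseTable):
        df = data.to_frame()
    else:
        df = pd.DataFrame(data)
    df = df.dropna(axis=0, how="any")
    n, p = df.shape
    if p < 2:
        raise ValueError("need at least two variables")
    if n <= p:
        raise ValueError(f"n={n} <= p={p}: too few complete cases for a stable GGM")

    arr = df.to_numpy(dtype=float)
    kinds = [_classify(arr[:, j], policy.max_categories) for j in range(p)]
    if policy.bin_deciles:
        for j in range(p):
            if kinds[j] != "ordinal":
                arr[:, j] = _decile_bin(arr[:, j])
                kinds[j] = "ordinal"

    names = [str(c) for c in df.columns]
    R = np.eye(p)
    methods: dict[tuple[str, str], str] = {}
    for i in range(p):
        for j in range(i + 1, p):
            if kinds[i] == "ordinal" and kinds[j] == "ordinal":
                r = polychoric_pair(arr[:, i], arr[:, j])
                m = "polychoric"
            elif kinds[i] == "continuous" and kinds[j] == "continuous":
                r = float(stats.pearsonr(arr[:, i], arr[:, j])[0])
                m = "pearson"
            else:
                r = float(stats.spearmanr(arr[:, i], arr[:, j])[0])
                m = "spearman"
            R[i, j] = R[j, i] = r
            methods[(names[i], names[j])] = m

    repaired = False
    if np.linalg.eigvalsh(R)[0] < -policy.psd_tol:
        R = np.asarray(corr_nearest(R, threshold=policy.psd_tol, n_fact=200))
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        repaired = True
    return CorrelationMatrix(R, names, methods, repaired, n)
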