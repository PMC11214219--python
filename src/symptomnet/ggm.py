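"""Sparse Gaussian graphical model estimation: graphical lasso + EBIC.

The estimator maximizes the L1-penalized Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

over positive-definite precision matrices Theta (the diagonal is not
penalized).  The solver is the classic block coordinate-descent of the
graphical lasso: each column update is a lasso regression on the current
working covariance W, warm-started along a descending lambda path.  The
penalty is selected by the Extended BIC

    EBIC(lambda) = -2 l(Theta) + E log(n) + 4 E gamma log(p)

with l = (n/2)[log det Theta - tr(S Theta)] and E the number of nonzero
upper-triangle edges; ties prefer the sparser (larger-lambda) model.

Edge weights of the resulting network are partial correlations,
w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).

The inner kernels are numba-compiled because the stability and comparison
modules re-estimate the network tens of thousands of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .polychoric import CorrelationMatrix

__all__ = [
    "PrecisionMatrix",
    "PartialCorrelationNetwork",
    "glasso_fit",
    "precision_to_pcor",
    "default_lambda_grid",
    "select_lambda_ebic",
]

#: Edge weights with absolute value below this are stored as exact zeros.
EDGE_ZERO_TOL = 1e-10

DEFAULT_TOL = 1e-4
DEFAULT_MAX_SWEEPS = 10_000


class GlassoConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _glasso_inplace(S, lam, tol, max_sweeps, W, B):
    """Block coordinate-descent glasso; W (working covariance) and B (lasso
    coefficient columns) are updated in place for warm starts.  Returns
    (sweeps_used, final_max_change)."""
    p = S.shape[0]
    for i in range(p):
        W[i, i] = S[i, i]
    inner_tol = tol * 0.1
    delta = 0.0
    sweeps = 0
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            # lasso: min 0.5 b'W11 b - s12'b + lam|b|_1 by coordinate descent
            for _ in range(1000):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for m in range(p):
                        if m == j or m == k:
                            continue
                        r -= W[k, m] * B[m, j]
                    bk = _soft(r, lam) / W[k, k]
                    d = bk - B[k, j]
                    if d != 0.0:
                        B[k, j] = bk
                        ad = abs(d)
                        if ad > inner_delta:
                            inner_delta = ad
                if inner_delta < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for m in range(p):
                    if m == j:
                        continue
                    w += W[k, m] * B[m, j]
                d = abs(w - W[k, j])
                if d > delta:
                    delta = d
                W[k, j] = w
                W[j, k] = w
        sweeps = sweep + 1
        if delta < tol:
            break
    return sweeps, delta


@njit(cache=True)
def _theta_from_wb(W, B):
    """Recover Theta from the converged working covariance and lasso columns.

    theta_jj = 1/(w_jj - w12'b_j); theta_12 = -b_j theta_jj, so the exact
    zeros produced by soft-thresholding are preserved."""
    p = W.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        s = 0.0
        for k in range(p):
            if k != j:
                s += W[k, j] * B[k, j]
        tjj = 1.0 / (W[j, j] - s)
        theta[j, j] = tjj
        for k in range(p):
            if k != j:
                theta[k, j] = -B[k, j] * tjj
    for i in range(p):
        for j in range(i + 1, p):
            if theta[i, j] == 0.0 or theta[j, i] == 0.0:
                theta[i, j] = 0.0
                theta[j, i] = 0.0
            else:
                v = 0.5 * (theta[i, j] + theta[j, i])
                theta[i, j] = v
                theta[j, i] = v
    return theta


@njit(cache=True)
def _ebic_path(S, n, grid, gamma, tol, max_sweeps):
    """Warm-started glasso along a descending lambda grid; returns the
    EBIC-minimizing Theta (ties -> larger lambda) plus per-lambda
    diagnostics."""
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    nlam = grid.shape[0]
    ebics = np.empty(nlam)
    edge_counts = np.zeros(nlam, dtype=np.int64)
    sweeps_used = np.zeros(nlam, dtype=np.int64)
    best = np.inf
    best_idx = 0
    best_theta = np.eye(p)
    logp = np.log(p)
    logn = np.log(n)
    for g in range(nlam):
        sw, _ = _glasso_inplace(S, grid[g], tol, max_sweeps, W, B)
        sweeps_used[g] = sw
        theta = _theta_from_wb(W, B)
        L = np.linalg.cholesky(theta)
        logdet = 0.0
        for i in range(p):
            logdet += 2.0 * np.log(L[i, i])
        tr = 0.0
        for i in range(p):
            for j in range(p):
                tr += S[i, j] * theta[j, i]
        ll = 0.5 * n * (logdet - tr)
        E = 0
        for i in range(p):
            for j in range(i + 1, p):
                if theta[i, j] != 0.0:
                    E += 1
        eb = -2.0 * ll + E * logn + 4.0 * E * gamma * logp
        ebics[g] = eb
        edge_counts[g] = E
        if eb < best:
            best = eb
            best_idx = g
            best_theta = theta.copy()
    return best_theta, best_idx, ebics, edge_counts, sweeps_used


@njit(cache=True)
def _pcor_from_theta(theta, zero_tol):
    p = theta.shape[0]
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                v = -theta[i, j] / np.sqrt(theta[i, i] * theta[j, j])
                if abs(v) < zero_tol:
                    v = 0.0
                w[i, j] = v
    return w


# --- fast resampling support: correlation + network straight from data -----

@njit(cache=True)
def _pearson_matrix(X):
    n, p = X.shape
    S = np.eye(p)
    Z = np.empty((n, p))
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        v = 0.0
        for i in range(n):
            d = X[i, j] - m
            Z[i, j] = d
            v += d * d
        sd = np.sqrt(v)
        if sd == 0.0:
            return S, False
        for i in range(n):
            Z[i, j] /= sd
    for a in range(p):
        for b in range(a + 1, p):
            s = 0.0
            for i in range(n):
                s += Z[i, a] * Z[i, b]
            S[a, b] = s
            S[b, a] = s
    return S, True


@njit(cache=True)
def _rank_column(x):
    n = x.shape[0]
    order = np.argsort(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


@njit(cache=True)
def _corr_from_data(X, method):
    """method 0 = Pearson, 1 = Spearman."""
    if method == 1:
        n, p = X.shape
        Xr = np.empty((n, p))
        for j in range(p):
            Xr[:, j] = _rank_column(X[:, j])
        return _pearson_matrix(Xr)
    return _pearson_matrix(X)


@njit(cache=True)
def _log_grid(lmax, n_lam, ratio):
    grid = np.empty(n_lam)
    if n_lam == 1:
        grid[0] = lmax
        return grid
    llo = np.log(lmax * ratio)
    lhi = np.log(lmax)
    for g in range(n_lam):
        grid[g] = np.exp(lhi + (llo - lhi) * g / (n_lam - 1))
    return grid


@njit(cache=True)
def _network_from_data(X, method, n_lam, ratio, gamma, tol, max_sweeps):
    """Data -> correlation -> EBIC-selected partial-correlation weights.

    Returns (weights, ok); ok is False for degenerate (constant-column)
    input.  Used by the bootstrap and permutation loops."""
    p = X.shape[1]
    S, ok = _corr_from_data(X, method)
    if not ok:
        return np.zeros((p, p)), False
    lmax = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            a = abs(S[i, j])
            if a > lmax:
                lmax = a
    if lmax <= 0.0:
        return np.zeros((p, p)), True
    grid = _log_grid(lmax, n_lam, ratio)
    theta, _, _, _, _ = _ebic_path(S, X.shape[0], grid, gamma, tol, max_sweeps)
    return _pcor_from_theta(theta, EDGE_ZERO_TOL), True


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class PrecisionMatrix:
    theta: np.ndarray
    penalty_lambda: float
    converged: bool
    iterations: int
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        if np.any(np.diag(t) <= 0):
            raise ValueError("precision matrix must have positive diagonal")
        if np.linalg.eigvalsh(t)[0] <= 0:
            raise ValueError("precision matrix must be positive definite")
        self.theta = t


@dataclass
class PartialCorrelationNetwork:
    """Signed weighted undirected network of partial correlations."""

    weights: np.ndarray
    node_names: list[str]
    lambda_selected: float = 0.0
    ebic_gamma: float = 0.5
    n: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")
        if np.any(np.abs(w) >= 1):
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = w

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    rows.append((self.node_names[i], self.node_names[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, index=self.node_names, columns=self.node_names).to_csv(path)


def _as_matrix(S) -> tuple[np.ndarray, list[str]]:
    if isinstance(S, CorrelationMatrix):
        return S.values, list(S.node_names)
    S = np.asarray(S, dtype=float)
    return S, [f"V{i + 1}" for i in range(S.shape[0])]


def _check_input(Sm: np.ndarray) -> None:
    if not np.allclose(Sm, Sm.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if not np.allclose(np.diag(Sm), 1.0, atol=1e-8):
        raise ValueError("S must have unit diagonal")
    if np.linalg.eigvalsh(Sm)[0] < -1e-8:
        raise ValueError("S is indefinite; repair it upstream (nearest correlation matrix)")


def glasso_fit(
    S,
    lam: float,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> PrecisionMatrix:
    """One graphical-lasso fit at a fixed penalty ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Sm, names = _as_matrix(S)
    _check_input(Sm)
    p = Sm.shape[0]
    W = Sm.copy()
    B = np.zeros((p, p))
    sweeps, delta = _glasso_inplace(Sm, lam, tol, max_sweeps, W, B)
    theta = _theta_from_wb(W, B)
    if delta >= tol:
        Winv = np.linalg.inv(theta)
        gap = float(np.trace(Sm @ theta) - p + lam * np.sum(np.abs(theta - np.diag(np.diag(theta)))))
        raise GlassoConvergenceError(
            f"glasso did not converge in {max_sweeps} sweeps "
            f"(max change {delta:.2e}, duality gap {gap:.2e})"
        )
    return PrecisionMatrix(theta, float(lam), True, sweeps, names)


def precision_to_pcor(theta: PrecisionMatrix | np.ndarray) -> PartialCorrelationNetwork:
    """Partial-correlation weights w_ij = -theta_ij / sqrt(theta_ii theta_jj)."""
    if isinstance(theta, PrecisionMatrix):
        t = theta.theta
        names = theta.node_names or [f"V{i + 1}" for i in range(t.shape[0])]
        lam = theta.penalty_lambda
    else:
        t = np.asarray(theta, dtype=float)
        names = [f"V{i + 1}" for i in range(t.shape[0])]
        lam = 0.0
    if np.any(np.diag(t) <= 0):
        raise ValueError("precision diagonal must be positive")
    w = _pcor_from_theta(t, EDGE_ZERO_TOL)
    w = (w + w.T) / 2.0
    return PartialCorrelationNetwork(w, names, lambda_selected=lam)


def default_lambda_grid(S, n_points: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max off-diagonal |S_ij|."""
    Sm, _ = _as_matrix(S)
    lmax = float(np.max(np.abs(Sm - np.diag(np.diag(Sm)))))
    if lmax <= 0:
        lmax = 1e-4
    return np.asarray(_log_grid(lmax, n_points, ratio))


def select_lambda_ebic(
    S,
    n: int,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> PartialCorrelationNetwork:
    """Fit the whole lambda path and return the EBIC-selected network."""
    if n <= 0:
        raise ValueError("n must be positive")
    Sm, names = _as_matrix(S)
    _check_input(Sm)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Sm)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(grid <= 0):
        raise ValueError("lambda grid must be positive")
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be sorted descending")
    theta, idx, ebics, edge_counts, sweeps = _ebic_path(
        Sm, n, grid, gamma, tol, max_sweeps
    )
    net = precision_to_pcor(PrecisionMatrix(theta, float(grid[idx]), True, int(sweeps[idx]), names))
    net.lambda_selected = float(grid[idx])
    net.ebic_gamma = float(gamma)
    net.n = int(n)
    net.diagnostics = {
        "lambda_grid": grid.tolist(),
        "ebic": ebics.tolist(),
        "edge_counts": edge_counts.tolist(),
        "selected_index": int(idx),
        "sweeps": sweeps.tolist(),
    }
    return net


def network_from_data(
    X: np.ndarray,
    node_names: list[str] | None = None,
    method: str = "spearman",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    gamma: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> PartialCorrelationNetwork:
    """Fast path: raw data matrix -> EBIC-selected network (Pearson/Spearman).

    This is the kernel the bootstrap and permutation modules call once per
    resample; it skips the per-pair method policy of
    :func:`symptomnet.polychoric.build_correlation_matrix`.
    """
    X = np.ascontiguousarray(X, dtype=float)
    mcode = {"pearson": 0, "spearman": 1}[method]
    w, ok = _network_from_data(X, mcode, n_lambda, lambda_ratio, gamma, tol, max_sweeps)
    if not ok:
        raise ValueError("degenerate (constant) variable in data")
    names = node_names or [f"V{i + 1}" for i in range(X.shape[1])]
    w = (w + w.T) / 2.0
    return PartialCorrelationNetwork(w, names, n=X.shape[0], ebic_gamma=gamma)
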