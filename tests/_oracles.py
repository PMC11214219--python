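"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: geodesics by
exhaustive simple-path enumeration, partial correlations by the
residual-regression route on the implied covariance, and tetrachoric
correlation by a fine likelihood grid scan using scipy's bivariate normal
CDF.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.stats import multivariate_normal, norm


def enumerate_geodesics(w: np.ndarray, tol: float = 1e-12):
    """All-pairs shortest paths by enumerating every simple path.

    Returns (lengths, paths, node_betweenness, edge_betweenness) where the
    selected path per unordered pair (i<j) starts at i and is the
    lexicographically smallest among length ties (within ``tol``).
    """
    p = w.shape[0]
    with np.errstate(divide="ignore"):
        d = np.where(w != 0, 1.0 / np.abs(w), np.inf)
    np.fill_diagonal(d, 0.0)
    lengths = np.full((p, p), np.inf)
    np.fill_diagonal(lengths, 0.0)
    paths: dict[tuple[int, int], tuple[int, ...]] = {}
    node_b = np.zeros(p)
    edge_b: dict[tuple[int, int], int] = {
        (i, j): 0 for i in range(p) for j in range(i + 1, p) if w[i, j] != 0
    }
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            best_len = np.inf
            best_path = None
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (i,) + mid + (j,)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if not np.isfinite(d[a, b]):
                            ok = False
                            break
                        length += d[a, b]
                    if not ok:
                        continue
                    if length < best_len - tol or (
                        abs(length - best_len) <= tol
                        and (best_path is None or path < best_path)
                    ):
                        best_len = length
                        best_path = path
            if best_path is not None:
                lengths[i, j] = lengths[j, i] = best_len
                paths[(i, j)] = best_path
                for node in best_path[1:-1]:
                    node_b[node] += 1
                for a, b in zip(best_path[:-1], best_path[1:]):
                    edge_b[(min(a, b), max(a, b))] += 1
    return lengths, paths, node_b, edge_b


def pcor_residual_oracle(theta: np.ndarray) -> np.ndarray:
    """Partial correlations via residual covariances of the implied
    Gaussian: regress variables i and j on all others and correlate the
    residuals (population computation on C = theta^-1)."""
    C = np.linalg.inv(theta)
    p = C.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            if rest:
                Ckk = C[np.ix_(rest, rest)]
                Cik = C[np.ix_([i, j], rest)]
                R = C[np.ix_([i, j], [i, j])] - Cik @ np.linalg.solve(Ckk, Cik.T)
            else:
                R = C[np.ix_([i, j], [i, j])]
            r = R[0, 1] / np.sqrt(R[0, 0] * R[1, 1])
            out[i, j] = out[j, i] = r
    return out


def tetrachoric_grid_scan(table: np.ndarray, resolution: float = 1e-5) -> float:
    """Tetrachoric correlation of a 2x2 count table by likelihood scan.

    Thresholds fixed at the marginal inverse-normal estimates; rho found by
    a coarse-to-fine grid scan with scipy's bivariate normal CDF."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    tx = norm.ppf(table[0].sum() / n)
    ty = norm.ppf(table[:, 0].sum() / n)

    def loglik(rho: float) -> float:
        p11 = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([tx, ty])
        p1 = norm.cdf(tx)
        p2 = norm.cdf(ty)
        probs = np.array(
            [[p11, p1 - p11], [p2 - p11, 1 - p1 - p2 + p11]]
        )
        probs = np.maximum(probs, 1e-12)
        return float((table * np.log(probs)).sum())

    lo, hi = -0.999, 0.999
    for step in (1e-2, 1e-3, 1e-4, resolution):
        grid = np.clip(np.arange(lo, hi + step / 2, step), -0.999, 0.999)
        vals = [loglik(r) for r in grid]
        best = grid[int(np.argmax(vals))]
        lo, hi = max(-0.999, best - 2 * step), min(0.999, best + 2 * step)
    return float(best)
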