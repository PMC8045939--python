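"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible points instead of calling a solver, the OLS
oracle uses the closed-form slope formula, and the bounded-fit oracle is an
exhaustive grid search.
"""

from itertools import combinations, product

import numpy as np


def vertex_enumeration_lp(c, A_eq, b_eq, lb, ub, maximize=True, tol=1e-8):
    """Optimum of max/min c·x s.t. A_eq x = b_eq, lb <= x <= ub, by
    enumerating candidate vertices (n_fixed variables at a bound, the rest
    solved from the equalities). Only viable for small n."""
    c = np.asarray(c, float)
    A = np.atleast_2d(np.asarray(A_eq, float))
    b = np.asarray(b_eq, float)
    n = len(c)
    rank = np.linalg.matrix_rank(A)
    n_fixed = n - rank
    best = None
    best_x = None
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for pattern in product((0, 1), repeat=n_fixed):
            x = np.full(n, np.nan)
            for j, p in zip(fixed, pattern):
                x[j] = lb[j] if p == 0 else ub[j]
            if np.any(~np.isfinite(x[list(fixed)])):
                continue
            rhs = b - A[:, list(fixed)] @ x[list(fixed)]
            sol, res, rk, _ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            x[free] = sol
            if np.max(np.abs(A @ x - b)) > tol:
                continue
            if np.any(x < np.asarray(lb) - tol) or np.any(x > np.asarray(ub) + tol):
                continue
            val = float(c @ x)
            if best is None or (val > best if maximize else val < best):
                best, best_x = val, x.copy()
    return best, best_x


def ols_slope(x, y):
    """Closed-form OLS slope and its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    slope = np.sum((x - xb) * (y - yb)) / sxx
    resid = y - (yb + slope * (x - xb))
    n = len(x)
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx) if n > 2 else np.nan
    return slope, se

def grid_search_bounded_fit(y, M, lo=0.0, hi=4.0, step=0.01):
    """Exhaustive grid minimizer of ||y - M a||^2 over the box [lo, hi]^p."""
    M = np.atleast_2d(np.asarray(M, float))
    if M.shape[0] != len(y):
        M = M.T
    grid = np.arange(lo, hi + step / 2, step)
    p = M.shape[1]
    best, best_a = None, None
    if p == 1:
        for a in grid:
            r = y - M[:, 0] * a
            v = float(r @ r)
            if best is None or v < best:
                best, best_a = v, np.array([a])
    elif p == 2:
        # vectorize over the second coordinate for speed
        for a0 in grid:
            R = y[:, None] - np.outer(M[:, 0], np.full(len(grid), a0)) \
                - M[:, 1][:, None] * grid[None, :]
            vals = np.einsum("ij,ij->j", R, R)
            j = int(np.argmin(vals))
            if best is None or vals[j] < best:
                best, best_a = float(vals[j]), np.array([a0, grid[j]])
    else:
        raise NotImplementedError("grid oracle supports <= 2 substrates")
    return best_a, best
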