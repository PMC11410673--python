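"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route that shares no code with the
implementation it checks: direct quadratic programming for optimal control,
explicit double sums for network variance, exhaustive enumeration for
permutation tests and dominance analysis.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm
from scipy.sparse.linalg import spsolve


def discrete_qp_energy(
    a: np.ndarray,
    b_diag: np.ndarray,
    x0: np.ndarray,
    x_t: np.ndarray,
    horizon: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 400,
) -> float:
    """Optimal control energy by direct minimization of the discretized cost.

    The continuous problem is discretized exactly on ``n_steps`` intervals
    (zero-order-hold input); the resulting equality-constrained quadratic
    program over all states and inputs is solved through its KKT system with
    a generic sparse LU factorization.  Returns sum_k dt * ||u_k||^2.
    """
    n = a.shape[0]
    big_n = n_steps
    dt = horizon / big_n
    ad = expm(a * dt)
    # zero-order-hold input matrix: int_0^dt e^{A s} ds  B
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = a
    aug[:n, n:] = np.eye(n)
    gd = expm(aug * dt)[:n, n:]
    bd = gd @ np.diag(b_diag)

    # unknowns: x_1..x_{N-1} (x_N fixed), u_0..u_{N-1}, lambda_1..lambda_N
    nx = (big_n - 1) * n
    nu = big_n * n
    nl = big_n * n
    dim = nx + nu + nl

    def xi(k):  # x_k, k in 1..N-1
        return slice((k - 1) * n, k * n)

    def ui(k):  # u_k, k in 0..N-1
        return slice(nx + k * n, nx + (k + 1) * n)

    def li(k):  # lambda_k, k in 1..N
        return slice(nx + nu + (k - 1) * n, nx + nu + k * n)

    rows, cols, vals = [], [], []
    rhs = np.zeros(dim)

    def put(rs, cs, block):
        r0, c0 = rs.start, cs.start
        for i in range(n):
            for j in range(n):
                v = block[i, j]
                if v != 0.0:
                    rows.append(r0 + i)
                    cols.append(c0 + j)
                    vals.append(v)

    eye = np.eye(n)
    # stationarity wrt x_k: 2 dt (x_k - xT) + lambda_k - Ad^T lambda_{k+1} = 0
    for k in range(1, big_n):
        put(xi(k), xi(k), 2 * dt * eye)
        put(xi(k), li(k), eye)
        put(xi(k), li(k + 1), -ad.T)
        rhs[xi(k)] = 2 * dt * x_t
    # stationarity wrt u_k: 2 rho dt u_k - Bd^T lambda_{k+1} = 0
    for k in range(big_n):
        put(ui(k), ui(k), 2 * rho * dt * eye)
        put(ui(k), li(k + 1), -bd.T)
    # dynamics: x_{k+1} - Ad x_k - Bd u_k = 0 (x_0, x_N fixed)
    for k in range(big_n):
        r = li(k + 1)
        if k + 1 <= big_n - 1:
            put(r, xi(k + 1), eye)
        else:
            rhs[r] -= x_t  # x_N = xT moves to rhs
        if k >= 1:
            put(r, xi(k), -ad)
        else:
            rhs[r] += ad @ x0
        put(r, ui(k), -bd)
    kkt = sp.csc_matrix((vals, (rows, cols)), shape=(dim, dim))
    sol = spsolve(kkt, rhs)
    u = sol[nx : nx + nu].reshape(big_n, n)
    return float(dt * (u**2).sum())


def brute_effective_resistance(weights: np.ndarray) -> np.ndarray:
    """Pairwise effective resistance from the explicit e_i - e_j quadratic form."""
    n = weights.shape[0]
    lap = np.diag(weights.sum(axis=1)) - weights
    q = np.linalg.pinv(lap)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            e = np.zeros(n)
            e[i] += 1
            e[j] -= 1
            out[i, j] = e @ q @ e
    return out


def brute_network_variance(omega: np.ndarray, values: np.ndarray) -> float:
    """Explicit O(n^2) double sum over the rescaled distribution."""
    p = values - values.min()
    p = p / p.sum()
    n = len(p)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += p[i] * p[j] * omega[i, j]
    return 0.5 * total


def enumerate_ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p for the two-sample t statistic."""
    from scipy.stats import ttest_ind

    pooled = np.concatenate([a, b])
    na = len(a)
    t_obs = abs(ttest_ind(a, b, equal_var=True).statistic)
    count = total = 0
    for left in combinations(range(len(pooled)), na):
        left = list(left)
        right = [i for i in range(len(pooled)) if i not in left]
        t = abs(ttest_ind(pooled[left], pooled[right], equal_var=True).statistic)
        if t >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def enumerate_domain_p(values: np.ndarray, member_count: int, observed_median: float) -> float:
    """Exact one-sided p for a domain median over all assignments."""
    count = total = 0
    for idx in combinations(range(len(values)), member_count):
        if np.median(values[list(idx)]) >= observed_median - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_dominance(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominance by literal subset enumeration with statsmodels OLS fits."""
    import statsmodels.api as sm

    n, p = x.shape
    xs = (x - x.mean(0)) / x.std(0)

    def r2(cols):
        if not cols:
            return 0.0
        design = sm.add_constant(xs[:, list(cols)])
        return sm.OLS(y, design).fit().rsquared

    dom = np.zeros(p)
    for i in range(p):
        rest = [j for j in range(p) if j != i]
        by_size = []
        for k in range(p):
            incs = [r2(set(s) | {i}) - r2(set(s)) for s in combinations(rest, k)]
            by_size.append(np.mean(incs))
        dom[i] = np.mean(by_size)
    return dom, r2(set(range(p)))
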