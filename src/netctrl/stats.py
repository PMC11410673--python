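"""Statistics on a transition-energy matrix: asymmetry, source/target
variability, relay (intermediate-state) analysis, domain-level permutation
tests and the energy-distance relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import comb

from .energy import StateMap, TransitionEnergyMatrix

__all__ = [
    "AsymmetryReport",
    "RelayReport",
    "PermutationTestResult",
    "asymmetry_measures",
    "variability_test",
    "relay_analysis",
    "domain_median_test",
    "distance_energy_relation",
    "permutation_ttest",
]


@dataclass
class AsymmetryReport:
    """Directional structure of a square transition-energy matrix.

    ``delta[i, j] = E(i -> j) - E(j -> i)`` (antisymmetric);
    ``reach_minus_leave[j]`` averages ``delta[:, j]`` over sources, so
    positive values mark states harder to reach than to leave.

    ``target_sd[i]`` is the s.d. of row i's off-diagonal entries -- the
    variability of energy as the *target* varies.  ``source_sd[j]`` is the
    s.d. of column j's off-diagonal entries -- variability as the *source*
    varies.  Under drift dynamics the target's identity dominates the
    transition cost, so variability across targets exceeds variability
    across sources.
    """

    delta: np.ndarray
    reach_minus_leave: np.ndarray
    source_sd: np.ndarray
    target_sd: np.ndarray
    state_labels: list[str]


@dataclass
class RelayReport:
    relayed_fraction: float
    best_intermediate: dict[tuple[int, int], int]
    intermediate_counts: np.ndarray


@dataclass
class PermutationTestResult:
    t: float
    p: float
    cohens_d: float
    n_perm: int


def _require_square(te: TransitionEnergyMatrix) -> np.ndarray:
    e = te.energies
    if e.shape[0] != e.shape[1]:
        raise ValueError(f"transition matrix must be square, got {e.shape}")
    return e


def _offdiag_sd(values: np.ndarray, axis: int) -> np.ndarray:
    """Standard deviation along rows (axis=1) or columns (axis=0), diagonal excluded."""
    k = values.shape[0]
    mask = ~np.eye(k, dtype=bool)
    out = np.empty(k)
    for idx in range(k):
        v = values[idx, mask[idx]] if axis == 1 else values[mask[:, idx], idx]
        out[idx] = v.std(ddof=1) if v.size > 1 else 0.0
    return out


def asymmetry_measures(te: TransitionEnergyMatrix) -> AsymmetryReport:
    e = _require_square(te)
    delta = e - e.T
    k = e.shape[0]
    # mean over the k-1 other states (diagonal term of delta is 0)
    reach_minus_leave = delta.sum(axis=0) / max(k - 1, 1)
    return AsymmetryReport(
        delta=delta,
        reach_minus_leave=reach_minus_leave,
        source_sd=_offdiag_sd(e, axis=0),
        target_sd=_offdiag_sd(e, axis=1),
        state_labels=list(te.source_labels),
    )


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def permutation_ttest(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool | None = None,
) -> PermutationTestResult:
    """Two-sided two-sample permutation t-test with add-one correction.

    Labels are permuted between the pooled samples; the effect size is
    Cohen's d with pooled standard deviation.  With ``exact=True`` (or when
    the number of distinct splits is below ``n_perm``) all splits are
    enumerated instead of sampled.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = _cohens_d(a, b)
    if a.var(ddof=0) + b.var(ddof=0) == 0 and a.mean() == b.mean():
        return PermutationTestResult(t=0.0, p=1.0, cohens_d=0.0, n_perm=0)
    t_obs = sps.ttest_ind(a, b, equal_var=True).statistic
    pooled = np.concatenate([a, b])
    na = a.size
    n_splits = comb(pooled.size, na, exact=True)
    if exact is None:
        exact = n_splits <= n_perm
    if exact:
        count = 0
        total = 0
        idx_all = np.arange(pooled.size)
        for left in combinations(idx_all, na):
            left = np.array(left)
            right = np.setdiff1d(idx_all, left, assume_unique=True)
            t = sps.ttest_ind(pooled[left], pooled[right], equal_var=True).statistic
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
            total += 1
        # enumeration includes the observed split; p is the exact tail fraction
        p = count / total
        return PermutationTestResult(t=float(t_obs), p=float(p), cohens_d=d, n_perm=total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = sps.ttest_ind(perm[:na], perm[na:], equal_var=True).statistic
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(t=float(t_obs), p=float(p), cohens_d=d, n_perm=n_perm)


def variability_test(
    te: TransitionEnergyMatrix, n_perm: int = 10_000, seed: int | None = None
) -> PermutationTestResult:
    """Are target (column) standard deviations larger than source (row) ones?

    Unpaired two-sided permutation t-test on the per-state s.d. vectors.
    """
    e = _require_square(te)
    if e.shape[0] < 3:
        raise ValueError("need at least 3 states")
    rep = asymmetry_measures(te)
    return permutation_ttest(rep.target_sd, rep.source_sd, n_perm=n_perm, seed=seed)


def relay_analysis(te: TransitionEnergyMatrix) -> RelayReport:
    """Fraction of ordered pairs for which a single-intermediate two-leg path
    is cheaper than the direct transition."""
    e = _require_square(te)
    k = e.shape[0]
    best: dict[tuple[int, int], int] = {}
    counts = np.zeros(k, dtype=int)
    relayed = 0
    total = 0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            total += 1
            others = [m for m in range(k) if m != i and m != j]
            if not others:
                continue
            costs = np.array([e[i, m] + e[m, j] for m in others])
            m_best = int(np.argmin(costs))
            if costs[m_best] < e[i, j]:
                relayed += 1
                best[(i, j)] = others[m_best]
                counts[others[m_best]] += 1
    frac = relayed / total if total else 0.0
    return RelayReport(
        relayed_fraction=frac, best_intermediate=best, intermediate_counts=counts
    )


def domain_median_test(
    per_state_values: Sequence[float],
    domain_labels: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> dict:
    """One-sided permutation test of each domain's median against chance.

    Only labelled states enter the null pool; values are shuffled over the
    labelled states, and p is the (add-one corrected) fraction of
    permutations whose domain median is at least the observed one.  With
    ``exact=True`` all assignments of the domain's size are enumerated.
    """
    values = np.asarray(per_state_values, dtype=float)
    labels = np.asarray(list(domain_labels), dtype=object)
    labelled = np.array([lab is not None and lab == lab and lab != "" for lab in labels])
    pool = values[labelled]
    pool_labels = labels[labelled]
    if pool.size == 0:
        raise ValueError("no labelled states: every domain has zero members")
    domains = [d for d in dict.fromkeys(pool_labels)]
    out = {}
    rng = np.random.default_rng(seed)
    for dom in domains:
        member = pool_labels == dom
        kd = int(member.sum())
        if kd == 0:
            raise ValueError(f"domain {dom!r} has zero members")
        obs = np.median(pool[member])
        if exact:
            count = sum(
                1
                for idx in combinations(range(pool.size), kd)
                if np.median(pool[list(idx)]) >= obs - 1e-12
            )
            total = comb(pool.size, kd, exact=True)
            out[dom] = count / total
        else:
            count = 0
            for _ in range(n_perm):
                pick = rng.choice(pool.size, size=kd, replace=False)
                if np.median(pool[pick]) >= obs - 1e-12:
                    count += 1
            out[dom] = (1 + count) / (1 + n_perm)
    return out


def distance_energy_relation(
    states: Sequence[StateMap], te: TransitionEnergyMatrix
) -> tuple[float, float]:
    """Spearman correlation between pairwise Euclidean state distance and
    transition energy over all ordered off-diagonal pairs."""
    e = _require_square(te)
    k = e.shape[0]
    if len(states) != k:
        raise ValueError("states must match the transition matrix")
    x = np.stack([s.values for s in states])
    dists, energies = [], []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(x[i] - x[j])
            if d == 0:
                raise ValueError(f"states {i} and {j} are identical; distance degenerate")
            dists.append(d)
            energies.append(e[i, j])
    if len(dists) < 3:
        raise ValueError("need at least 3 state pairs")
    rho, p = sps.spearmanr(dists, energies)
    return float(rho), float(p)
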