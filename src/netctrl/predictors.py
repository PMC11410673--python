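"""Predictors of transition cost: per-state characterization table, partial
rank correlations and dominance analysis.

Each target state is characterized by its map's mean and standard deviation,
its rank correlations with connectome node metrics (binary degree, strength,
participation) and with a cortical hierarchy map, and its network variance on
the connectome; these are related to the mean energy required to reach the
state.  Dominance analysis partitions the full-model R^2 across predictors by
averaging each predictor's incremental R^2 over all 2^p - 1 submodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .energy import StateMap, TransitionEnergyMatrix
from .graph import (
    Connectome,
    PairDistanceMatrix,
    effective_resistance_matrix,
    network_variance,
    node_metrics,
)

__all__ = [
    "PredictorReport",
    "state_predictor_table",
    "partial_spearman",
    "dominance_analysis",
    "predictor_report",
]

# the five state characterizations entering the partial-correlation and
# dominance analyses (map mean and s.d. are nuisance covariates, not predictors)
PREDICTORS = [
    "corr_degree",
    "corr_strength",
    "corr_participation",
    "corr_hierarchy",
    "network_variance",
]


@dataclass
class PredictorReport:
    table: pd.DataFrame
    partials: pd.DataFrame
    dominance: pd.Series
    r_squared: float


def state_predictor_table(
    states: Sequence[StateMap],
    connectome: Connectome,
    hierarchy_map: np.ndarray,
    te: TransitionEnergyMatrix,
    partition: Sequence | None = None,
    resistance: PairDistanceMatrix | None = None,
) -> pd.DataFrame:
    """Per-state predictor table with the mean energy-to-reach column.

    ``hierarchy_map`` is an externally supplied per-node vector (e.g. the
    unimodal-transmodal functional gradient).  ``partition`` defaults to a
    single module (participation 0 everywhere) when not given.
    """
    if partition is None:
        partition = np.zeros(connectome.n, dtype=int)
    metrics = node_metrics(connectome, partition)
    if resistance is None:
        resistance = effective_resistance_matrix(connectome)
    hierarchy_map = np.asarray(hierarchy_map, dtype=float)
    e = te.energies
    if e.shape[1] != len(states):
        raise ValueError("transition matrix columns must match states")
    mask = ~np.eye(e.shape[0], dtype=bool) if e.shape[0] == e.shape[1] else np.ones(
        e.shape, dtype=bool
    )

    def safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan  # constant vector: correlation undefined, flagged as NaN
        return float(sps.spearmanr(a, b).statistic)

    rows = []
    for j, s in enumerate(states):
        v = s.values
        rows.append(
            {
                "state": s.label or f"state_{j}",
                "map_mean": float(v.mean()),
                "map_sd": float(v.std(ddof=1)),
                "corr_degree": safe_spearman(v, metrics.binary_degree),
                "corr_strength": safe_spearman(v, metrics.strength),
                "corr_participation": safe_spearman(v, metrics.participation),
                "corr_hierarchy": safe_spearman(v, hierarchy_map),
                "network_variance": network_variance(resistance, v),
                "energy_to_reach": float(e[mask[:, j], j].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("state")


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average", axis=0)


def partial_spearman(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation of y and x given covariates.

    All variables are rank-transformed (average ranks for ties); y and x are
    regressed on the covariate ranks (with intercept) and the residuals are
    correlated.  With no covariates this reduces to the plain Spearman rho.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = y.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        ry, rx = _rank(y), _rank(x)
        res_y = ry - ry.mean()
        res_x = rx - rx.mean()
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        k = z.shape[1]
        if n < k + 4:
            raise ValueError("need at least k+4 observations")
        design = np.column_stack([np.ones(n), _rank(z)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariates")
        ry, rx = _rank(y), _rank(x)
        res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    denom = np.linalg.norm(res_y) * np.linalg.norm(res_x)
    if denom == 0:
        return 0.0, 1.0
    rho = float(res_y @ res_x / denom)
    rho = min(1.0, max(-1.0, rho))
    dof = n - 2 - k
    if dof <= 0 or abs(rho) == 1.0:
        return rho, 0.0 if abs(rho) == 1.0 else 1.0
    t = rho * np.sqrt(dof / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), dof)
    return rho, float(p)


def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    n = y.size
    design = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / tss)


def dominance_analysis(
    y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
) -> tuple[pd.Series, float]:
    """Total dominance of each predictor and the full-model R^2.

    Total dominance of predictor i is its incremental R^2 when added to a
    submodel, averaged first within each submodel size and then across sizes
    (including the null model).  The dominances sum to the full-model
    (unadjusted) R^2.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if p > 15:
        raise ValueError("exhaustive dominance limited to p <= 15 predictors")
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    if not np.all(np.isfinite(xs)):
        bad = [i for i in range(p) if X[:, i].std() == 0]
        raise ValueError(f"constant predictor columns: {bad}")
    cond = np.linalg.cond(np.column_stack([np.ones(n), xs]))
    if cond > 1e8:
        corr = np.corrcoef(xs, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"collinear predictors (condition {cond:.3g}); worst pair columns {i} and {j}"
        )
    if names is None:
        names = [f"x{i}" for i in range(p)]

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2(subset: frozenset) -> float:
        if subset not in r2_cache:
            r2_cache[subset] = _r_squared(y, xs[:, sorted(subset)])
        return r2_cache[subset]

    dominance = np.zeros(p)
    others = list(range(p))
    for i in range(p):
        rest = [j for j in others if j != i]
        size_means = []
        for k in range(p):  # submodel sizes 0..p-1
            incs = [
                r2(frozenset(s) | {i}) - r2(frozenset(s))
                for s in combinations(rest, k)
            ]
            size_means.append(np.mean(incs))
        dominance[i] = np.mean(size_means)
    full = r2(frozenset(range(p)))
    return pd.Series(dominance, index=list(names)), full


def predictor_report(
    states: Sequence[StateMap],
    connectome: Connectome,
    hierarchy_map: np.ndarray,
    te: TransitionEnergyMatrix,
    partition: Sequence | None = None,
) -> PredictorReport:
    """Full predictor analysis: table, partial rank correlations (controlling
    map mean and s.d.) and dominance decomposition of energy-to-reach."""
    table = state_predictor_table(states, connectome, hierarchy_map, te, partition)
    y = table["energy_to_reach"].to_numpy()
    covars = table[["map_mean", "map_sd"]].to_numpy()
    partial_rows = []
    for name in PREDICTORS:
        x = table[name].to_numpy()
        if np.any(~np.isfinite(x)):
            partial_rows.append({"predictor": name, "rho": np.nan, "p": np.nan})
            continue
        rho, p = partial_spearman(y, x, covars)
        partial_rows.append({"predictor": name, "rho": rho, "p": p})
    partials = pd.DataFrame(partial_rows).set_index("predictor")
    dom_cols = [c for c in PREDICTORS if np.all(np.isfinite(table[c].to_numpy()))]
    dominance, r2 = dominance_analysis(y, table[dom_cols].to_numpy(), dom_cols)
    return PredictorReport(table=table, partials=partials, dominance=dominance, r_squared=r2)
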