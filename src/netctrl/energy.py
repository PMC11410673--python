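"""Optimal control energy between activation topographies.

The brain is modelled as a linear time-invariant system

    dx/dt = A_norm x(t) + B u(t)

driven between a source state ``x0`` and a target state ``xT`` over a finite
horizon ``T``.  The optimal input minimizes

    J(u) = int_0^T (xT - x)^T (xT - x) + rho u^T u  dt

subject to the dynamics and both endpoint constraints.  The first-order
optimality (Pontryagin) conditions give a linear state-costate system

    d/dt [x; l] = [[A, -B B^T / (2 rho)], [-2 I, -A^T]] [x; l] + [0; 2 xT]

whose two-point boundary value problem is solved in closed form through the
matrix exponential of the (augmented) state-costate operator; the trajectory
is then evaluated forward from t=0.  The reported energy is the input
magnitude integral ``int u^T u dt`` (the rho weighting is part of the cost,
not of the energy).

``minimum_energy`` is the rho -> infinity limit: the endpoint-constrained
least-input-energy solution through the finite-horizon controllability
Gramian, used as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .graph import NormalizedSystem

__all__ = [
    "StateMap",
    "ControlWeights",
    "TransitionResult",
    "TransitionEnergyMatrix",
    "ConditioningError",
    "build_control_weights",
    "optimal_transition",
    "transition_energies",
    "minimum_energy",
    "transition_energy_matrix",
]


class ConditioningError(np.linalg.LinAlgError):
    """Raised when a boundary-value or Gramian system is too ill-conditioned."""


@dataclass
class StateMap:
    """One activation topography over regions (a state vector x)."""

    values: np.ndarray
    label: str = ""
    unit_norm: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"state map {self.label!r} contains non-finite values")
        if self.unit_norm:
            nrm = np.linalg.norm(v)
            if nrm == 0:
                raise ValueError("cannot unit-normalize the zero map")
            v = v / nrm
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ControlWeights:
    """Diagonal control-input matrix B.

    mode:
      * ``uniform``        -- all ones (identity B).
      * ``thickness_delta``-- 1 + d_i for a signed Cohen's-d map of cortical
                              thickness change (atrophy lowers input capacity).
      * ``receptor``       -- 1 + minmax01(map) for a non-negative density map.
      * ``unit_mean_map``  -- map rescaled to unit mean.
    """

    diag: np.ndarray
    mode: str = "uniform"
    source_map: np.ndarray | None = None
    kappa: str = "all"

    def __post_init__(self) -> None:
        d = np.asarray(self.diag, dtype=float).ravel()
        if np.any(d <= 0):
            raise ValueError("all control weights must be positive")
        self.diag = d

    @property
    def n(self) -> int:
        return self.diag.shape[0]


def build_control_weights(
    mode: str, map: np.ndarray | None = None, n: int | None = None
) -> ControlWeights:
    """Build the diagonal B matrix from a regional modulation map."""
    if mode == "uniform":
        if n is None:
            if map is None:
                raise ValueError("uniform mode needs n or a map for its length")
            n = len(np.asarray(map).ravel())
        return ControlWeights(diag=np.ones(n), mode="uniform")
    if map is None:
        raise ValueError(f"mode {mode!r} requires a map")
    m = np.asarray(map, dtype=float).ravel()
    if mode == "thickness_delta":
        if np.any(m <= -1):
            raise ValueError(
                "thickness_delta map has Cohen's d <= -1; control weight would be non-positive"
            )
        diag = 1.0 + m
    elif mode == "receptor":
        rng = m.max() - m.min()
        if rng <= 0:
            raise ValueError("receptor map is constant; min-max scaling degenerate")
        diag = 1.0 + (m - m.min()) / rng
    elif mode == "unit_mean_map":
        total = m.sum()
        if total <= 0 or np.any(m <= 0):
            raise ValueError("unit_mean_map requires a strictly positive map")
        diag = m * (m.size / total)
    else:
        raise ValueError(f"unknown control-weight mode {mode!r}")
    return ControlWeights(diag=diag, mode=mode, source_map=m)


@dataclass
class TransitionResult:
    energy: float
    trajectory: np.ndarray  # n x n_steps
    inputs: np.ndarray  # n x n_steps
    endpoint_error: float
    times: np.ndarray
    warning: str | None = None


@dataclass
class TransitionEnergyMatrix:
    """K_source x K_target optimal-energy table (rows = sources, cols = targets)."""

    energies: np.ndarray
    source_labels: list[str]
    target_labels: list[str]
    params: dict = field(default_factory=dict)

    @property
    def is_square(self) -> bool:
        return (
            self.energies.shape[0] == self.energies.shape[1]
            and self.source_labels == self.target_labels
        )


class _TpbvOperators:
    """Precomputed propagators of the state-costate system for one (A, B, rho, T).

    M = [[A, -B B^T/(2 rho)], [-2 I, -A^T]]; the constant forcing is
    b = [0; 2 xT].  Phi_T = exp(M T) and G_T = int_0^T exp(M s) ds give the
    endpoint map; Phi_dt / G_dt step the sampled trajectory.
    """

    def __init__(
        self,
        a: np.ndarray,
        b_diag: np.ndarray,
        rho: float,
        horizon: float,
        n_steps: int,
    ):
        n = a.shape[0]
        self.n = n
        self.rho = rho
        self.b_diag = b_diag
        self.n_steps = n_steps
        self.dt = horizon / (n_steps - 1)
        bbt = np.diag(b_diag**2)
        m = np.block([[a, -bbt / (2.0 * rho)], [-2.0 * np.eye(n), -a.T]])
        self.phi_T, self.g_T = _expm_with_integral(m, horizon)
        self.phi_dt, self.g_dt = _expm_with_integral(m, self.dt)

    def solve_costate(self, x0: np.ndarray, x_t: np.ndarray) -> np.ndarray:
        """Initial costates (columns) making x(T) hit xT; x0/x_t are n x K."""
        n = self.n
        e11 = self.phi_T[:n, :n]
        e12 = self.phi_T[:n, n:]
        g12 = self.g_T[:n, n:]
        rhs = x_t - e11 @ x0 - 2.0 * (g12 @ x_t)
        cond = np.linalg.cond(e12)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConditioningError(
                f"boundary matrix condition number {cond:.3g} exceeds 1e12"
            )
        return np.linalg.solve(e12, rhs)


def _expm_with_integral(m: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (exp(M t), int_0^t exp(M s) ds) via one augmented exponential."""
    k = m.shape[0]
    aug = np.zeros((2 * k, 2 * k))
    aug[:k, :k] = m
    aug[:k, k:] = np.eye(k)
    e = expm(aug * t)
    return e[:k, :k], e[:k, k:]


def _propagate_energies(
    ops: _TpbvOperators,
    x0: np.ndarray,
    lam0: np.ndarray,
    x_t: np.ndarray,
    keep_trajectory: bool = False,
):
    """Forward-evaluate the closed-form trajectories and integrate u^T u.

    x0, lam0, x_t: n x K column stacks.  Energy by trapezoidal quadrature on
    ``n_steps`` samples.
    """
    n, k = x0.shape
    z = np.vstack([x0, lam0])
    forcing = np.vstack([np.zeros_like(x_t), 2.0 * x_t])
    g_forcing = ops.g_dt @ forcing
    scale = ops.b_diag[:, None] / (2.0 * ops.rho)

    energy = np.zeros(k)
    traj = inputs = None
    if keep_trajectory:
        traj = np.empty((n, ops.n_steps, k))
        inputs = np.empty((n, ops.n_steps, k))

    u = -scale * z[n:]
    energy += 0.5 * (u**2).sum(axis=0)
    if keep_trajectory:
        traj[:, 0, :] = z[:n]
        inputs[:, 0, :] = u
    for step in range(1, ops.n_steps):
        z = ops.phi_dt @ z + g_forcing
        u = -scale * z[n:]
        w = 0.5 if step == ops.n_steps - 1 else 1.0
        energy += w * (u**2).sum(axis=0)
        if keep_trajectory:
            traj[:, step, :] = z[:n]
            inputs[:, step, :] = u
    energy *= ops.dt
    endpoint_error = np.linalg.norm(z[:n] - x_t, axis=0) / np.maximum(
        np.linalg.norm(x_t, axis=0), 1.0
    )
    return energy, endpoint_error, traj, inputs


def optimal_transition(
    system: NormalizedSystem,
    weights: ControlWeights,
    x0: StateMap,
    xT: StateMap,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
    endpoint_tol: float = 1e-6,
) -> TransitionResult:
    """Optimal control transition from ``x0`` to ``xT``; see module docstring.

    Returns the input-energy integral, the sampled optimal trajectory and
    inputs, and the relative endpoint error of the forward-evaluated solution.
    """
    if T <= 0 or rho <= 0:
        raise ValueError("T and rho must be positive")
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100 for reliable quadrature")
    n = system.n
    if x0.n != n or xT.n != n or weights.n != n:
        raise ValueError("state/weight dimensions do not match the system")
    ops = _TpbvOperators(system.a_norm, weights.diag, rho, T, n_steps)
    x0c = x0.values[:, None]
    xtc = xT.values[:, None]
    lam0 = ops.solve_costate(x0c, xtc)
    energy, err, traj, inputs = _propagate_energies(
        ops, x0c, lam0, xtc, keep_trajectory=True
    )
    warning = None
    if err[0] > endpoint_tol:
        warning = f"endpoint error {err[0]:.3g} above tolerance {endpoint_tol:.3g}"
    return TransitionResult(
        energy=float(energy[0]),
        trajectory=traj[:, :, 0],
        inputs=inputs[:, :, 0],
        endpoint_error=float(err[0]),
        times=np.linspace(0.0, T, n_steps),
        warning=warning,
    )


def transition_energies(
    system: NormalizedSystem,
    weights: ControlWeights,
    sources: np.ndarray,
    targets: np.ndarray,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
) -> np.ndarray:
    """Vectorized K_source x K_target grid of optimal-transition energies.

    ``sources`` and ``targets`` are ``n x K`` column stacks.  One propagator
    set is shared across the grid; per target column all sources are solved
    and propagated together.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    ops = _TpbvOperators(system.a_norm, weights.diag, rho, T, n_steps)
    ks, kt = sources.shape[1], targets.shape[1]
    out = np.empty((ks, kt))
    for j in range(kt):
        xt = np.repeat(targets[:, [j]], ks, axis=1)
        lam0 = ops.solve_costate(sources, xt)
        energy, err, _, _ = _propagate_energies(ops, sources, lam0, xt)
        if np.any(err > 1e-4):
            raise ConditioningError(
                f"endpoint error up to {err.max():.3g} for target column {j}"
            )
        out[:, j] = energy
    return out


def minimum_energy(
    system: NormalizedSystem,
    weights: ControlWeights,
    x0: StateMap,
    xT: StateMap,
    T: float = 1.0,
    cond_threshold: float = 1e12,
) -> float:
    """Endpoint-constrained minimum control energy via the controllability Gramian.

    E_min = v^T W^-1 v with v = xT - e^{A T} x0 and
    W = int_0^T e^{A s} B B^T e^{A^T s} ds  (Van Loan block-exponential).
    """
    a = system.a_norm
    n = a.shape[0]
    bbt = np.diag(weights.diag**2)
    blk = np.zeros((2 * n, 2 * n))
    blk[:n, :n] = -a
    blk[:n, n:] = bbt
    blk[n:, n:] = a.T
    e = expm(blk * T)
    ead = e[n:, n:].T  # e^{A T}
    gram = ead @ e[:n, n:]
    gram = (gram + gram.T) / 2.0
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise ConditioningError(
            f"Gramian condition number {cond:.3g} exceeds {cond_threshold:.3g}"
        )
    v = xT.values - ead @ x0.values
    return float(v @ np.linalg.solve(gram, v))


def transition_energy_matrix(
    system: NormalizedSystem,
    weights: ControlWeights,
    sources: Sequence[StateMap],
    targets: Sequence[StateMap] | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
) -> TransitionEnergyMatrix:
    """All-pairs optimal transition energies between named states.

    Rows are source states, columns target states; ``targets`` defaults to
    ``sources`` (the all-to-all table).
    """
    if targets is None:
        targets = list(sources)
    if len(sources) == 0 or len(targets) == 0:
        raise ValueError("need at least one source and one target state")
    src = np.stack([s.values for s in sources], axis=1)
    tgt = np.stack([t.values for t in targets], axis=1)
    try:
        energies = transition_energies(system, weights, src, tgt, T, rho, n_steps)
    except ConditioningError as exc:
        raise ConditioningError(f"transition grid failed: {exc}") from exc
    return TransitionEnergyMatrix(
        energies=energies,
        source_labels=[s.label or f"state_{i}" for i, s in enumerate(sources)],
        target_labels=[t.label or f"state_{j}" for j, t in enumerate(targets)],
        params={
            "T": T,
            "rho": rho,
            "c": system.c,
            "n_steps": n_steps,
            "mode": weights.mode,
        },
    )
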