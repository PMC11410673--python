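"""Spin-rotation spatial null maps and significance screening of
regional modulation maps.

The spin test generates null versions of a cortical map by randomly rotating
parcel centroids on the sphere and re-assigning each parcel the value of the
closest rotated parcel (per hemisphere, with mirrored rotations across
hemispheres).  Rotated maps keep the original map's value distribution and
spatial autocorrelation while randomizing its anatomical alignment, which is
exactly the null needed when asking whether the *location* of a modulation
map (receptor density, atrophy pattern) matters for transition energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .energy import (
    StateMap,
    build_control_weights,
    transition_energy_matrix,
)
from .graph import NormalizedSystem

__all__ = [
    "SpinNullSet",
    "ScreenResult",
    "spin_permutations",
    "apply_spin",
    "morans_i",
    "inverse_distance_weights",
    "screen_modulation_map",
]


@dataclass
class SpinNullSet:
    """Index arrays of spin permutations.

    ``permutations[r, i]`` is the source parcel whose value parcel ``i``
    receives in rotation ``r``.  With ``assignment='bijective'`` every row is
    a permutation; with ``'nearest'`` (the standard method) values may be
    duplicated or dropped.
    """

    permutations: np.ndarray
    n_rot: int
    seed: int
    assignment: str = "nearest"


@dataclass
class ScreenResult:
    """Per-target percentages of significantly facilitated / disfacilitated
    transitions, with the underlying per-transition p-values."""

    pct_facilitated: np.ndarray  # per target state
    pct_disfacilitated: np.ndarray
    p_facilitation: np.ndarray  # K x K, diagonal NaN
    p_disfacilitation: np.ndarray
    alpha: float
    target_labels: list[str] = field(default_factory=list)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_permutations(
    sphere_coords: np.ndarray,
    hemisphere,
    n_rot: int,
    seed: int = 0,
    assignment: str = "nearest",
) -> SpinNullSet:
    """Build spin-test permutations from per-hemisphere spherical centroids.

    One rotation is sampled per null and applied to the left hemisphere; its
    mirror image (reflection across the sagittal plane) is applied to the
    right, so bilateral symmetry of the nulls matches that of the data.
    """
    coords = np.asarray(sphere_coords, dtype=float)
    hemi = np.asarray(list(hemisphere), dtype=object)
    n = coords.shape[0]
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn("sphere coordinates not unit-norm; renormalizing", stacklevel=2)
        coords = coords / norms[:, None]
    if assignment not in ("nearest", "bijective"):
        raise ValueError(f"unknown assignment {assignment!r}")
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n_rot, n), dtype=int)
    hemi_idx = {h: np.nonzero(hemi == h)[0] for h in np.unique(hemi)}
    for r in range(n_rot):
        rot_l = _random_rotation(rng)
        for h, idx in hemi_idx.items():
            rot = rot_l if h == "L" else mirror @ rot_l @ mirror
            rotated = coords[idx] @ rot.T
            d = cdist(coords[idx], rotated)
            if assignment == "nearest":
                perms[r, idx] = idx[np.argmin(d, axis=1)]
            else:
                rows, cols = linear_sum_assignment(d)
                perms[r, idx[rows]] = idx[cols]
    return SpinNullSet(permutations=perms, n_rot=n_rot, seed=seed, assignment=assignment)


def apply_spin(spin_set: SpinNullSet, values: np.ndarray) -> np.ndarray:
    """Rotated versions of a map: rows are nulls, columns parcels."""
    return np.asarray(values, dtype=float)[spin_set.permutations]


def inverse_distance_weights(coords3d: np.ndarray) -> np.ndarray:
    """Default spatial weight matrix for Moran's I: 1/d, zero diagonal."""
    coords3d = np.asarray(coords3d, dtype=float)
    d = cdist(coords3d, coords3d)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(values: np.ndarray, weight_matrix: np.ndarray) -> float:
    """Moran's spatial autocorrelation I under the supplied weights."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weight_matrix, dtype=float)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("constant map: Moran's I undefined")
    s0 = w.sum()
    return float(len(x) / s0 * (z @ w @ z) / denom)


def screen_modulation_map(
    system: NormalizedSystem,
    states: list[StateMap],
    modulation_map: np.ndarray,
    mode: str,
    spin_set: SpinNullSet,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
    alpha: float = 0.05,
) -> ScreenResult:
    """Screen a modulation map against its spin nulls, transition by transition.

    For every ordered state pair the energy under the empirical map's control
    weights is compared with the distribution over rotated maps' weights.
    Facilitation p = (1 + #{null energy <= empirical}) / (1 + n_rot);
    disfacilitation analogously (two one-sided tests).  Per target state, the
    percentage of source states significant at ``alpha`` is reported.
    """
    if mode not in ("thickness_delta", "receptor"):
        raise ValueError(f"mode must be thickness_delta or receptor, got {mode!r}")
    if spin_set.n_rot < 20:
        raise ValueError("n_rot < 20: p-value resolution too coarse")

    def energies_for(map_values: np.ndarray) -> np.ndarray:
        weights = build_control_weights(mode, map_values)
        te = transition_energy_matrix(
            system, weights, states, T=T, rho=rho, n_steps=n_steps
        )
        return te.energies

    emp = energies_for(np.asarray(modulation_map, dtype=float))
    k = emp.shape[0]
    null_maps = apply_spin(spin_set, modulation_map)
    count_le = np.zeros((k, k))
    count_ge = np.zeros((k, k))
    for r in range(spin_set.n_rot):
        nulls = energies_for(null_maps[r])
        count_le += nulls <= emp
        count_ge += nulls >= emp
    p_fac = (1 + count_le) / (1 + spin_set.n_rot)
    p_dis = (1 + count_ge) / (1 + spin_set.n_rot)
    np.fill_diagonal(p_fac, np.nan)
    np.fill_diagonal(p_dis, np.nan)
    offdiag = ~np.eye(k, dtype=bool)
    n_sources = k - 1
    pct_fac = 100.0 * np.sum((p_fac <= alpha) & offdiag, axis=0) / n_sources
    pct_dis = 100.0 * np.sum((p_dis <= alpha) & offdiag, axis=0) / n_sources
    return ScreenResult(
        pct_facilitated=pct_fac,
        pct_disfacilitated=pct_dis,
        p_facilitation=p_fac,
        p_disfacilitation=p_dis,
        alpha=alpha,
        target_labels=[s.label or f"state_{i}" for i, s in enumerate(states)],
    )
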