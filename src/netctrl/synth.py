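"""Seeded generators for every input the analysis consumes.

The generators emulate the statistical character of the real inputs:

* spatially embedded weighted connectomes (~68-100 nodes, ~25-30% density)
  whose connection probability decays with Euclidean distance and whose
  weights are positively skewed and anticorrelated with edge length;
* non-negative spatially autocorrelated activation maps with heterogeneous
  means and variances (meta-analytic-association-like);
* signed effect-size (Cohen's d) atrophy maps with extremes near +0.87/-0.59;
* non-negative skewed receptor-density maps;
* per-hemisphere unit-sphere parcel centroids with mirror symmetry.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .energy import StateMap
from .graph import Connectome

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "make_coordinates",
    "make_connectome",
    "make_participant_ensemble",
    "make_state_maps",
    "make_modulation_map",
    "make_dataset",
]

BRAIN_RADIUS_MM = 70.0  # approximate hemispheric shell radius


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic pipeline.

    n=68 parcels at 27% density match the consensus-connectome scale of the
    analyses this package reproduces; decay_length and smoothness are in mm.
    """

    n: int = 68
    density: float = 0.27
    decay_length: float = 40.0
    smoothness: float = 30.0
    k_states: int = 10
    k_participants: int = 20
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.decay_length <= 0 or self.smoothness <= 0:
            raise ValueError("length scales must be positive")


@dataclass
class SyntheticDataset:
    connectome: Connectome
    participants: list[Connectome]
    states: list[StateMap]
    modulation_maps: dict[str, dict] = field(default_factory=dict)
    hierarchy_map: np.ndarray | None = None
    config: GeneratorConfig | None = None


def make_coordinates(n: int, seed: int = 0):
    """Parcel centroids: per-hemisphere unit-sphere coords, 3-D mm coords and
    hemisphere tags (n/2 parcels per hemisphere).

    Each hemisphere's spherical coordinates cover the FULL unit sphere, the
    way a hemisphere's cortical surface inflates to a complete sphere in
    surface registration (this is what makes spin rotations value-preserving).
    The right hemisphere mirrors the left's sampling, so the ensemble is
    mirror-symmetric in expectation.  The 3-D embedding places the two
    hemispheric shells side by side along the x axis.
    """
    if n < 8 or n % 2:
        raise ValueError("n must be even and >= 8")
    rng = np.random.default_rng(seed)
    half = n // 2
    left = rng.normal(size=(half, 3))
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = rng.normal(size=(half, 3))
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    right = right * np.array([-1.0, 1.0, 1.0])  # mirrored sampling convention
    sphere = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half, dtype=object)
    radius = BRAIN_RADIUS_MM * 0.65
    offset = BRAIN_RADIUS_MM * 0.45
    coords3d = sphere * radius
    coords3d[:half, 0] -= offset
    coords3d[half:, 0] += offset
    return coords3d, hemisphere, sphere


def make_connectome(
    coords3d: np.ndarray,
    density: float = 0.27,
    decay_length: float = 40.0,
    seed: int = 0,
    hemisphere=None,
    sphere_coords=None,
    labels=None,
    max_retry: int = 20,
) -> Connectome:
    """Spatially embedded random connectome.

    Connection probability follows an exponential distance kernel
    ``alpha * exp(-d / decay_length)`` with ``alpha`` calibrated so the
    expected density matches the request; weights are lognormal, damped by
    the same kernel so that weight anticorrelates with length.  The graph is
    regenerated until connected and within +-2 percentage points of the
    requested density.
    """
    coords3d = np.asarray(coords3d, dtype=float)
    n = coords3d.shape[0]
    d = cdist(coords3d, coords3d)
    iu, ju = np.triu_indices(n, 1)
    kernel = np.exp(-d[iu, ju] / decay_length)
    n_pairs = len(iu)
    m = int(round(density * n_pairs))
    if m < n - 1:
        raise ValueError(f"density {density} gives {m} edges; need >= {n - 1} for connectivity")

    rng = np.random.default_rng(seed)
    for _ in range(max_retry):
        pick = rng.choice(n_pairs, size=m, replace=False, p=kernel / kernel.sum())
        w = np.zeros((n, n))
        wts = np.exp(rng.normal(0.0, 0.6, size=m)) * np.exp(
            -d[iu[pick], ju[pick]] / decay_length
        )
        w[iu[pick], ju[pick]] = wts
        w += w.T
        conn = Connectome(
            weights=w,
            coords3d=coords3d,
            hemisphere=hemisphere,
            sphere_coords=sphere_coords,
            labels=labels,
        )
        if conn.is_connected():
            return conn
    raise RuntimeError(
        f"could not realize a connected graph at density {density} in {max_retry} draws"
    )


def make_participant_ensemble(
    base: Connectome, k: int, noise_sd: float = 0.2, swap_frac: float = 0.05, seed: int = 0
) -> list[Connectome]:
    """Participant-level jittered copies of a ground-truth connectome.

    Each participant keeps most of the base edge set, with multiplicative
    lognormal weight noise and a small fraction of edges dropped and replaced
    by random (distance-plausible) non-edges.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(base.n, 1)
    present = base.weights[iu, ju] > 0
    edge_idx = np.nonzero(present)[0]
    non_idx = np.nonzero(~present)[0]
    out = []
    for _ in range(k):
        w = base.weights.copy()
        if noise_sd > 0:
            noise = np.exp(rng.normal(0.0, noise_sd, size=edge_idx.size))
            w[iu[edge_idx], ju[edge_idx]] *= noise
            w[ju[edge_idx], iu[edge_idx]] = w[iu[edge_idx], ju[edge_idx]]
        n_swap = int(round(swap_frac * edge_idx.size)) if noise_sd > 0 else 0
        if n_swap and non_idx.size:
            drop = rng.choice(edge_idx, size=n_swap, replace=False)
            add = rng.choice(non_idx, size=min(n_swap, non_idx.size), replace=False)
            mean_w = base.weights[iu[edge_idx], ju[edge_idx]].mean()
            for p in drop:
                w[iu[p], ju[p]] = w[ju[p], iu[p]] = 0.0
            for p in add:
                wt = mean_w * np.exp(rng.normal(0.0, noise_sd))
                w[iu[p], ju[p]] = w[ju[p], iu[p]] = wt
        out.append(
            Connectome(
                weights=w,
                coords3d=base.coords3d,
                hemisphere=base.hemisphere,
                sphere_coords=base.sphere_coords,
                labels=base.labels,
            )
        )
    return out


def _smooth_field(
    coords3d: np.ndarray, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially autocorrelated field: distance-kernel mixing of white noise."""
    d = cdist(coords3d, coords3d)
    k = np.exp(-d / smoothness)
    z = rng.normal(size=coords3d.shape[0])
    f = k @ z
    return (f - f.mean()) / f.std()


def make_state_maps(
    coords3d: np.ndarray,
    k_states: int = 10,
    smoothness: float = 30.0,
    mean_range: tuple[float, float] = (0.2, 6.0),
    sd_range: tuple[float, float] = (0.1, 3.0),
    seed: int = 0,
    nonnegative: bool = True,
) -> list[StateMap]:
    """Smooth activation topographies with heterogeneous means and s.d.s.

    Each map is a smooth field rescaled to a mean and s.d. drawn from the
    given ranges, clipped at zero when ``nonnegative`` (meta-analytic
    association values are non-negative).  The mean and s.d. are drawn
    log-uniformly and *coupled* through a shared per-map magnitude position
    (with jitter): large maps are large in both mean and spread, the way a
    term's overall prevalence scales its whole association map.  Across the
    default ranges, per-map magnitudes span about a 30-fold range.
    """
    if sd_range[0] <= 0:
        raise ValueError("sd_range must exclude 0")
    if mean_range[0] <= 0:
        raise ValueError("mean_range must be positive")
    rng = np.random.default_rng(seed)
    log_mr = np.log(mean_range)
    log_sr = np.log(sd_range)
    maps = []
    for s in range(k_states):
        f = _smooth_field(coords3d, smoothness, rng)
        u = rng.uniform()
        mu = float(np.exp(log_mr[0] + u * (log_mr[1] - log_mr[0])))
        v_pos = float(np.clip(u + rng.normal(0.0, 0.1), 0.0, 1.0))
        sd = float(np.exp(log_sr[0] + v_pos * (log_sr[1] - log_sr[0])))
        v = mu + sd * f
        if nonnegative:
            v = np.clip(v, 0.0, None)
        maps.append(StateMap(values=v, label=f"state_{s}"))
    return maps


def make_modulation_map(
    coords3d: np.ndarray,
    kind: str,
    effect_regions: np.ndarray | list | None = None,
    magnitude: float = 0.0,
    smoothness: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Receptor-like or atrophy-like modulation map with planted ground truth.

    ``receptor``: non-negative, positively skewed density map (extremes at the
    planted regions when ``magnitude > 0``).  ``atrophy``: signed Cohen's-d
    map scaled to extremes near +0.87 / -0.59; a positive ``magnitude`` adds a
    localized boost (or, if negative, deficit) at ``effect_regions``.
    """
    n = np.asarray(coords3d).shape[0]
    effect = np.asarray(effect_regions, dtype=int) if effect_regions is not None else np.array([], dtype=int)
    if effect.size and (effect.min() < 0 or effect.max() >= n):
        raise ValueError("effect_regions outside parcel range")
    rng = np.random.default_rng(seed)
    f = _smooth_field(coords3d, smoothness, rng)
    if kind == "receptor":
        if magnitude < 0:
            raise ValueError("receptor magnitude must be >= 0")
        base = np.exp(0.6 * f)  # positively skewed, non-negative
        if magnitude > 0 and effect.size:
            base[effect] += magnitude * base.max()
        values = base
    elif kind == "atrophy":
        if not -1 < magnitude < 1:
            raise ValueError("atrophy magnitude must be a Cohen's d in (-1, 1)")
        pos, neg = 0.87, 0.59  # Cohen's-d extremes of case-control thickness maps
        values = np.where(f > 0, f / f.max() * pos, f / (-f.min()) * neg)
        if magnitude != 0 and effect.size:
            values[effect] = magnitude
    else:
        raise ValueError(f"unknown modulation kind {kind!r}")
    truth = {
        "kind": kind,
        "effect_regions": effect.tolist() if magnitude != 0 else [],
        "magnitude": magnitude,
    }
    return values, truth


def make_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Full synthetic dataset under one seed: connectome, participant
    ensemble, state maps, one receptor-like and one atrophy-like modulation
    map, and a smooth hierarchy map."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    coords3d, hemi, sphere = make_coordinates(cfg.n, int(seeds[0]))
    conn = make_connectome(
        coords3d,
        cfg.density,
        cfg.decay_length,
        int(seeds[1]),
        hemisphere=hemi,
        sphere_coords=sphere,
    )
    participants = make_participant_ensemble(
        conn, cfg.k_participants, cfg.noise_sd, seed=int(seeds[2])
    )
    states = make_state_maps(
        coords3d, cfg.k_states, cfg.smoothness, seed=int(seeds[3])
    )
    receptor, truth_r = make_modulation_map(
        coords3d, "receptor", smoothness=cfg.smoothness, seed=int(seeds[4])
    )
    atrophy, truth_a = make_modulation_map(
        coords3d, "atrophy", smoothness=cfg.smoothness, seed=int(seeds[4]) + 1
    )
    hierarchy = _smooth_field(coords3d, cfg.smoothness, np.random.default_rng(int(seeds[5])))
    return SyntheticDataset(
        connectome=conn,
        participants=participants,
        states=states,
        modulation_maps={
            "receptor": {"values": receptor, "truth": truth_r},
            "atrophy": {"values": atrophy, "truth": truth_a},
        },
        hierarchy_map=hierarchy,
        config=cfg,
    )
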