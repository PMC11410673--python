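"""Rewired-network null models and empirical-vs-null energy comparisons.

Two null families disambiguate topology from geometry:

* degree-preserving (Maslov-Sneppen) rewiring: edge swaps randomize topology
  while keeping the exact binary degree sequence and the exact multiset of
  edge weights;
* geometry-preserving rewiring: swaps are additionally constrained so the
  multiset of edge-length distance bins is unchanged, and weights are
  re-assigned within bins by length rank, approximately preserving the edge
  length distribution and the weight-length relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy import ControlWeights, StateMap, transition_energy_matrix
from .graph import Connectome, normalize_adjacency

__all__ = [
    "NullEnsemble",
    "NullComparison",
    "rewire_degree_preserving",
    "rewire_geometry_preserving",
    "build_null_ensemble",
    "compare_empirical_vs_nulls",
]

log = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    kind: str  # degree_preserving | geometry_preserving
    members: list[Connectome]
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class NullComparison:
    empirical_mean_energy: float
    null_mean_energies: np.ndarray
    p_lower: float
    kind: str
    n_failed: int = 0
    params: dict = field(default_factory=dict)


def _edge_list(conn: Connectome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.nonzero(np.triu(conn.weights, 1))
    return iu.copy(), ju.copy(), conn.weights[iu, ju].copy()


def _swap_once(
    edges: dict[tuple[int, int], float],
    keys: list[tuple[int, int]],
    e1: int,
    e2: int,
    flip: bool,
    accept=None,
) -> bool:
    """Attempt one Maslov-Sneppen swap in place; returns True on success."""
    if e1 == e2:
        return False
    a, b = keys[e1]
    c, d = keys[e2]
    if flip:
        c, d = d, c
    # new edges (a, d) and (c, b)
    if len({a, b, c, d}) < 4:
        return False
    new1 = (min(a, d), max(a, d))
    new2 = (min(c, b), max(c, b))
    if new1 in edges or new2 in edges:
        return False
    if accept is not None and not accept((a, b), (c, d), new1, new2):
        return False
    w1 = edges.pop((a, b) if (a, b) in edges else (b, a))
    w2 = edges.pop((c, d) if (c, d) in edges else (d, c))
    edges[new1] = w1
    edges[new2] = w2
    keys[e1] = new1
    keys[e2] = new2
    return True


def _edges_to_connectome(base: Connectome, edges: dict[tuple[int, int], float]) -> Connectome:
    w = np.zeros_like(base.weights)
    for (i, j), wt in edges.items():
        w[i, j] = w[j, i] = wt
    return Connectome(
        weights=w,
        labels=base.labels,
        coords3d=base.coords3d,
        hemisphere=base.hemisphere,
        sphere_coords=base.sphere_coords,
    )


def _connected(edges: dict[tuple[int, int], float], n: int) -> bool:
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return bool(seen.all())


def _rewire(
    conn: Connectome,
    n_swap_per_edge: int,
    rng: np.random.Generator,
    accept=None,
    max_attempt_factor: int = 100,
    n_retry: int = 50,
) -> dict[tuple[int, int], float]:
    iu, ju, wts = _edge_list(conn)
    n_edges = len(iu)
    if n_edges < 2:
        raise ValueError("not enough edges to swap")
    target_swaps = n_swap_per_edge * n_edges
    for _ in range(n_retry):
        edges = {(int(i), int(j)): float(w) for i, j, w in zip(iu, ju, wts)}
        keys = list(edges.keys())
        done = 0
        attempts = 0
        max_attempts = max_attempt_factor * target_swaps
        chunk = 8192
        while done < target_swaps and attempts < max_attempts:
            pairs = rng.integers(0, n_edges, size=(chunk, 2))
            flips = rng.random(chunk) < 0.5
            for (e1, e2), flip in zip(pairs, flips):
                attempts += 1
                if _swap_once(edges, keys, int(e1), int(e2), bool(flip), accept=accept):
                    done += 1
                    if done >= target_swaps:
                        break
                if attempts >= max_attempts:
                    break
        if done < target_swaps:
            raise RuntimeError(
                f"swap budget exhausted: {done}/{target_swaps} swaps after {attempts} attempts"
            )
        if _connected(edges, conn.n):
            return edges
        log.debug("rewired graph disconnected; resampling")
    raise RuntimeError(f"no connected rewiring found in {n_retry} attempts")


def rewire_degree_preserving(
    connectome: Connectome, n_swap_per_edge: int = 10, seed: int | None = None
) -> Connectome:
    """Maslov-Sneppen rewiring: exact binary degree sequence, exact weight
    multiset, connectivity re-checked (resampled on failure)."""
    connectome.require_connected()
    rng = np.random.default_rng(seed)
    edges = _rewire(connectome, n_swap_per_edge, rng)
    return _edges_to_connectome(connectome, edges)


def rewire_geometry_preserving(
    connectome: Connectome,
    n_bins: int = 10,
    n_swap_per_edge: int = 10,
    seed: int | None = None,
) -> Connectome:
    """Distance-binned rewiring preserving degree sequence, weight multiset,
    the binned edge-length histogram and (approximately) the weight-length
    relationship.

    Swaps are accepted only when the multiset of distance bins of the two
    edges is unchanged; afterwards the original weights are re-assigned
    within each bin so that weight rank follows length rank as in the
    empirical network.
    """
    if connectome.coords3d is None:
        raise ValueError("coords3d required for geometry-preserving rewiring")
    connectome.require_connected()
    rng = np.random.default_rng(seed)
    coords = connectome.coords3d
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)

    iu, ju, wts = _edge_list(connectome)
    lengths = dist[iu, ju]
    edges_bins = np.linspace(lengths.min(), lengths.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(lengths, bins=edges_bins)
    # merge bins with < 2 edges into their lower neighbour
    keep = [0]
    for b in range(1, n_bins):
        if counts[keep[-1]] < 2:
            counts[keep[-1]] += counts[b]
        else:
            keep.append(b)
            counts[b] = counts[b]
    boundaries = np.concatenate(
        [[edges_bins[0]], [edges_bins[b + 1] for b in keep[:-1]], [edges_bins[-1]]]
    )
    if len(keep) < n_bins:
        log.info("merged %d underpopulated distance bins", n_bins - len(keep))

    bin_matrix = np.clip(
        np.digitize(dist, boundaries) - 1, 0, len(boundaries) - 2
    )

    def bin_of(i: int, j: int) -> int:
        return int(bin_matrix[i, j])

    def accept(old1, old2, new1, new2) -> bool:
        b1, b2 = bin_matrix[old1], bin_matrix[old2]
        n1, n2 = bin_matrix[new1], bin_matrix[new2]
        return (b1 == n1 and b2 == n2) or (b1 == n2 and b2 == n1)

    # bin-constrained swaps have a low acceptance rate on small graphs
    edges = _rewire(connectome, n_swap_per_edge, rng, accept=accept, max_attempt_factor=2000)

    # re-assign weights within bins by length rank (empirical rank order)
    emp_bins = np.array([bin_of(i, j) for i, j in zip(iu, ju)])
    new_keys = list(edges.keys())
    new_bins = np.array([bin_of(i, j) for i, j in new_keys])
    new_lengths = np.array([dist[i, j] for i, j in new_keys])
    for b in np.unique(emp_bins):
        emp_idx = np.nonzero(emp_bins == b)[0]
        new_idx = np.nonzero(new_bins == b)[0]
        assert len(emp_idx) == len(new_idx), "bin occupancy changed during rewiring"
        # shorter new edges get the weights the shorter empirical edges had
        emp_rank_w = wts[emp_idx][np.argsort(lengths[emp_idx])]
        order_new = np.argsort(new_lengths[new_idx])
        for pos, widx in enumerate(order_new):
            edges[new_keys[new_idx[widx]]] = float(emp_rank_w[pos])
    return _edges_to_connectome(connectome, edges)


def build_null_ensemble(
    connectome: Connectome,
    kind: str,
    n_members: int,
    seed: int = 0,
    n_swap_per_edge: int = 10,
    n_bins: int = 10,
) -> NullEnsemble:
    """Seeded ensemble of rewired nulls of the requested kind."""
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        member_seed = int(rng.integers(0, 2**31 - 1))
        if kind == "degree_preserving":
            members.append(
                rewire_degree_preserving(connectome, n_swap_per_edge, member_seed)
            )
        elif kind == "geometry_preserving":
            members.append(
                rewire_geometry_preserving(
                    connectome, n_bins, n_swap_per_edge, member_seed
                )
            )
        else:
            raise ValueError(f"unknown null kind {kind!r}")
    return NullEnsemble(kind=kind, members=members, seed=seed)


def compare_empirical_vs_nulls(
    connectome: Connectome,
    ensemble: NullEnsemble,
    states: list[StateMap],
    weights: ControlWeights,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 0.0,
    n_steps: int = 1000,
) -> NullComparison:
    """Mean all-to-all transition energy on the empirical connectome versus
    each re-normalized null member.

    ``p_lower = (1 + #{null mean <= empirical mean}) / (1 + n_members)`` is
    the non-parametric p for the hypothesis that the empirical network
    supports cheaper transitions.
    """
    if ensemble.n_members == 0:
        raise ValueError("empty null ensemble")

    def mean_energy(conn: Connectome) -> float:
        system = normalize_adjacency(conn, c=c)
        te = transition_energy_matrix(
            system, weights, states, T=T, rho=rho, n_steps=n_steps
        )
        e = te.energies
        mask = ~np.eye(e.shape[0], dtype=bool)
        return float(e[mask].mean())

    emp = mean_energy(connectome)
    nulls = []
    n_failed = 0
    for m, member in enumerate(ensemble.members):
        try:
            nulls.append(mean_energy(member))
        except Exception:  # noqa: BLE001 - per-member failures are excluded, counted
            log.warning("null member %d failed; excluded", m)
            n_failed += 1
    nulls = np.asarray(nulls)
    p = (1 + int((nulls <= emp).sum())) / (1 + len(nulls))
    return NullComparison(
        empirical_mean_energy=emp,
        null_mean_energies=nulls,
        p_lower=p,
        kind=ensemble.kind,
        n_failed=n_failed,
        params={"T": T, "rho": rho, "c": c, "n_steps": n_steps},
    )
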