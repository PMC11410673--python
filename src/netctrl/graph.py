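"""Connectome container, adjacency normalization, consensus construction,
effective resistance and network-based variance.

The connectome is a weighted, undirected, spatially embedded graph whose
adjacency matrix ``A`` acts as the drift operator of a linear dynamical
system.  Before control computations ``A`` is normalized as

    A_norm = A / (|lambda_max| + c) - I

so that the largest mode of the system is marginally stable (``c = 0``) or
decays (``c > 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Connectome",
    "NormalizedSystem",
    "PairDistanceMatrix",
    "NodeMetrics",
    "DegenerateInputError",
    "DisconnectedGraphError",
    "normalize_adjacency",
    "build_consensus",
    "effective_resistance_matrix",
    "network_variance",
    "node_metrics",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically degenerate
    (all-zero adjacency, constant map, ...)."""


class DisconnectedGraphError(ValueError):
    """Raised when a computation requires a connected graph.

    Carries the connected components in ``components``.
    """

    def __init__(self, components: list[set[int]]):
        self.components = components
        sizes = sorted((len(c) for c in components), reverse=True)
        super().__init__(
            f"graph is disconnected: {len(components)} components with sizes {sizes}"
        )


def _symmetrize(weights: np.ndarray) -> np.ndarray:
    asym = np.abs(weights - weights.T).max() if weights.size else 0.0
    if asym > 1e-8:
        warnings.warn(
            f"adjacency asymmetry {asym:.3g} exceeds 1e-8; symmetrizing as (A+A^T)/2",
            stacklevel=3,
        )
    return (weights + weights.T) / 2.0


@dataclass
class Connectome:
    """Weighted symmetric region graph with optional spatial embedding.

    Parameters
    ----------
    weights
        ``n x n`` non-negative symmetric matrix with zero diagonal.
    labels
        Region names, in matrix order.
    coords3d
        ``n x 3`` region centroids in mm.
    hemisphere
        Per-region ``"L"`` / ``"R"`` tags.
    sphere_coords
        ``n x 3`` unit-sphere centroids (used by spin nulls).
    """

    weights: np.ndarray
    labels: Sequence[str] | None = None
    coords3d: np.ndarray | None = None
    hemisphere: np.ndarray | None = None
    sphere_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        w = _symmetrize(w)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.labels is None:
            self.labels = [f"region_{i}" for i in range(self.n)]
        self.labels = list(self.labels)
        if len(self.labels) != self.n:
            raise ValueError("labels length does not match node count")
        if self.coords3d is not None:
            self.coords3d = np.asarray(self.coords3d, dtype=float).reshape(self.n, 3)
        if self.sphere_coords is not None:
            self.sphere_coords = np.asarray(self.sphere_coords, dtype=float).reshape(
                self.n, 3
            )
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere, dtype=object)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        n = self.n
        return float(np.count_nonzero(np.triu(self.weights, 1)) / (n * (n - 1) / 2))

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every existing edge (upper triangle order)."""
        if self.coords3d is None:
            raise ValueError("coords3d required for edge lengths")
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return np.linalg.norm(self.coords3d[iu] - self.coords3d[ju], axis=1)

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.weights)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_graph())

    def require_connected(self) -> None:
        g = self.to_graph()
        if not nx.is_connected(g):
            raise DisconnectedGraphError([set(c) for c in nx.connected_components(g)])


@dataclass
class NormalizedSystem:
    """Continuous-time drift matrix ``A_norm`` with its normalization constant.

    Invariant: the largest real eigenvalue of ``a_norm`` equals
    ``lambda_max / (lambda_max + c) - 1`` (0 when ``c = 0``).
    """

    a_norm: np.ndarray
    c: float
    lambda_max: float
    source: Connectome | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.a_norm.shape[0]


@dataclass
class PairDistanceMatrix:
    """Pairwise effective resistances ``omega``.

    ``convention`` records that omega itself is used as the squared
    distance d^2 in the network-variance statistic.
    """

    omega: np.ndarray
    convention: str = "omega_is_squared_distance"

    @property
    def n(self) -> int:
        return self.omega.shape[0]


@dataclass
class NodeMetrics:
    binary_degree: np.ndarray
    strength: np.ndarray
    participation: np.ndarray


def normalize_adjacency(
    connectome: Connectome, c: float = 0.0, relative: bool = False
) -> NormalizedSystem:
    """Normalize the adjacency to a stable (or marginally stable) drift matrix.

    ``A_norm = A / (|lambda_max| + c) - I``.  With ``relative=True`` the
    stabilization constant is ``c * |lambda_max|`` (e.g. ``c=0.01`` gives the
    1%-of-spectral-radius variant in which all modes decay).
    """
    a = connectome.weights
    lam = float(np.max(np.abs(np.linalg.eigvalsh(a))))
    if lam <= 0:
        raise DegenerateInputError("all-zero adjacency: spectral radius is 0")
    c_abs = float(c) * lam if relative else float(c)
    if c_abs < 0:
        raise ValueError("normalization constant c must be non-negative")
    a_norm = a / (lam + c_abs) - np.eye(connectome.n)
    return NormalizedSystem(a_norm=a_norm, c=c_abs, lambda_max=lam, source=connectome)


def _distance_matrix(coords3d: np.ndarray) -> np.ndarray:
    diff = coords3d[:, None, :] - coords3d[None, :, :]
    return np.linalg.norm(diff, axis=2)


def build_consensus(
    participants: Sequence[np.ndarray],
    coords3d: np.ndarray,
    hemisphere: Sequence[str],
    n_bins: int | None = None,
    labels: Sequence[str] | None = None,
    sphere_coords: np.ndarray | None = None,
) -> Connectome:
    """Distance-dependent group-consensus connectome.

    Builds a binary consensus mask per distance bin, separately for intra- and
    inter-hemispheric edges, keeping in each bin the edges most consistently
    present across participants (the number kept per bin equals the mean
    per-participant edge count in that bin, so that both the edge density and
    the edge-length distribution of individual participants are approximately
    preserved).  Retained edge weights are the mean of the corresponding
    non-zero participant weights.
    """
    if len(participants) == 0:
        raise ValueError("empty participant list")
    mats = [np.asarray(p, dtype=float) for p in participants]
    shape = mats[0].shape
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"participant {k} has shape {m.shape}, expected {shape}")
    n = shape[0]
    coords3d = np.asarray(coords3d, dtype=float).reshape(n, 3)
    hemi = np.asarray(list(hemisphere), dtype=object)
    stack = np.stack(mats)  # k x n x n
    k = stack.shape[0]

    if n_bins is None:
        mean_edges = np.mean([np.count_nonzero(np.triu(m, 1)) for m in mats])
        n_bins = max(1, int(np.ceil(np.sqrt(max(mean_edges, 1.0)))))

    dist = _distance_matrix(coords3d)
    iu, ju = np.triu_indices(n, 1)
    pair_dist = dist[iu, ju]
    presence = (stack[:, iu, ju] > 0)  # k x n_pairs
    prevalence = presence.sum(axis=0)  # number of participants with the edge
    mean_weight = np.where(
        prevalence > 0, stack[:, iu, ju].sum(axis=0) / np.maximum(prevalence, 1), 0.0
    )
    intra = hemi[iu] == hemi[ju]

    keep = np.zeros(len(iu), dtype=bool)
    for mask_class in (intra, ~intra):
        idx_class = np.nonzero(mask_class)[0]
        ever = idx_class[prevalence[idx_class] > 0]
        if ever.size == 0:
            continue
        d = pair_dist[ever]
        edges = np.linspace(d.min(), d.max() + 1e-9, n_bins + 1)
        which = np.digitize(d, edges) - 1
        which = np.clip(which, 0, n_bins - 1)
        for b in range(n_bins):
            in_bin = ever[which == b]
            if in_bin.size == 0:
                continue
            # mean number of edges a single participant has in this bin
            target = int(np.round(presence[:, in_bin].sum(axis=1).mean()))
            if target <= 0:
                continue
            # most consistently present first; ties broken by mean weight
            order = np.lexsort((-mean_weight[in_bin], -prevalence[in_bin]))
            keep[in_bin[order[: min(target, in_bin.size)]]] = True

    w = np.zeros((n, n))
    w[iu[keep], ju[keep]] = mean_weight[keep]
    w += w.T
    return Connectome(
        weights=w,
        labels=labels,
        coords3d=coords3d,
        hemisphere=hemi,
        sphere_coords=sphere_coords,
    )


def effective_resistance_matrix(connectome: Connectome) -> PairDistanceMatrix:
    """Effective resistance omega_ij from the Laplacian pseudoinverse.

    omega_ij = (e_i - e_j)^T Q (e_i - e_j) with Q = pinv(L); proportional to
    the commute time of a random walker between i and j.
    """
    connectome.require_connected()
    w = connectome.weights
    lap = np.diag(w.sum(axis=1)) - w
    q = np.linalg.pinv(lap)
    dq = np.diag(q)
    omega = dq[:, None] + dq[None, :] - 2 * q
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    return PairDistanceMatrix(omega=omega)


def network_variance(
    distances: PairDistanceMatrix, values: np.ndarray, rescale: bool = True
) -> float:
    """Variance of a distribution over graph nodes, var(p) = 1/2 sum p_i p_j d^2.

    By default the map is rescaled internally to a distribution: minimum
    subtracted, then divided by the sum.  With ``rescale=False`` the values
    are taken as a ready distribution (non-negative, summing to 1).
    Effective resistance is used as the squared distance.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] != distances.n:
        raise ValueError("map length does not match distance matrix")
    if rescale:
        p = x - x.min()
        total = p.sum()
        if total <= 0:
            raise DegenerateInputError("constant map: zero mass after rescaling")
        p = p / total
    else:
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("values must be a distribution when rescale=False")
        p = x
    return float(0.5 * p @ distances.omega @ p)


def node_metrics(connectome: Connectome, partition: Sequence) -> NodeMetrics:
    """Binary degree, strength and participation coefficient per node.

    Participation P_i = 1 - sum_m (s_im / s_i)^2 over modules m of the given
    partition; isolated nodes get P_i = 0.
    """
    part = np.asarray(list(partition))
    if part.shape[0] != connectome.n:
        raise ValueError("partition must cover all nodes")
    w = connectome.weights
    binary_degree = np.count_nonzero(w, axis=1)
    strength = w.sum(axis=1)
    modules = np.unique(part)
    s_im = np.stack([w[:, part == m].sum(axis=1) for m in modules], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = s_im / strength[:, None]
    frac[~np.isfinite(frac)] = 0.0
    participation = 1.0 - (frac**2).sum(axis=1)
    participation[strength == 0] = 0.0
    return NodeMetrics(
        binary_degree=binary_degree, strength=strength, participation=participation
    )
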