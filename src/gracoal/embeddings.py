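"""Disk and planar embeddings: Graphlet Spectral, Coalescent, GraCoal, GraSpring.

Coalescent-style embeddings map a network onto a 2D disk: the *angle*
encodes community structure (nodes that cluster get similar angles) and the
*radius* encodes topological importance (important nodes sit near the
centre, exploiting the exponentially growing circumference of the disk to
spread out scale-free networks).

The graphlet coalescent (GraCoal) embedding, for a chosen graphlet Gi,
proceeds in three steps:

1. embed the network in 2D with Graphlet Spectral embedding (Laplacian
   eigenmaps on the symmetrically normalized graphlet adjacency);
2. convert Cartesian coordinates to angles measured against the y-axis pole
   and place the nodes equidistantly on the disk periphery in that order;
3. assign radius ``rad_u = ln(r_u)`` where r_u ranks nodes by how often
   they touch Gi (highest count first).

The classical coalescent embedding (CE) baseline instead uses the degree
ranking and ``rad_u = beta*ln(r_u) + (1-beta)*ln(N)`` with
``beta = 1/(lambda-1)`` from a power-law fit of the degree distribution;
graphlet count distributions need not follow a power law, which is why the
GraCoal radius drops the degree-exponent weighting.

GraSpring is a force-directed (Fruchterman–Reingold) layout whose spring
tension is scaled by the normalized graphlet adjacency; seeded from the
spectral embedding it is fully deterministic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .graphlets import (
    GraphletAdjacency,
    count_graphlets,
    graphlet_adjacency,
    normalize_adjacency,
)
from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "CartesianEmbedding",
    "DiskEmbedding",
    "PowerLawFit",
    "graphlet_spectral_embedding",
    "angular_coordinates",
    "radial_gracoal",
    "radial_coalescent",
    "fit_power_law",
    "gracoal_embed",
    "coalescent_embed",
    "graspring_embed",
    "spectral_embed",
]

#: lower clamp for the fitted power-law exponent (keeps beta <= 2)
LAMBDA_MIN = 1.5


@dataclass(frozen=True)
class CartesianEmbedding:
    """2D coordinates for a subset of network nodes (sorted label order)."""

    nodes: tuple[str, ...]
    coords: np.ndarray  # shape (n, dim); dim = 2 everywhere downstream
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.nodes) or self.coords.shape[1] < 1:
            raise ValueError("coords must be (n_nodes, dim >= 1)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    def as_dict(self) -> dict[str, tuple[float, ...]]:
        return {u: tuple(float(c) for c in row) for u, row in zip(self.nodes, self.coords)}


@dataclass(frozen=True)
class DiskEmbedding:
    """Polar disk embedding: per-node angle (radians, [0, 2pi)) and radius."""

    nodes: tuple[str, ...]
    angles: np.ndarray
    radii: np.ndarray
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.angles.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("angles and radii must be length-n vectors")
        if (self.radii < 0).any():
            raise ValueError("radii must be nonnegative")

    def to_cartesian(self) -> CartesianEmbedding:
        """Convert with the y-axis-as-pole convention: x = r sin(a), y = r cos(a)."""
        x = self.radii * np.sin(self.angles)
        y = self.radii * np.cos(self.angles)
        return CartesianEmbedding(self.nodes, np.column_stack([x, y]), self.dropped)


@dataclass(frozen=True)
class PowerLawFit:
    """Continuous ML fit of P(d) ~ d^-lambda with d_min = 1."""

    lambda_hat: float
    clamped: bool = False

    @property
    def beta(self) -> float:
        return 1.0 / (self.lambda_hat - 1.0)


def fit_power_law(degrees: list[int] | np.ndarray, d_min: float = 1.0) -> PowerLawFit:
    """Continuous maximum-likelihood exponent of a power-law degree tail.

    ``lambda_hat = 1 + n / sum(ln(d_i / d_min))`` over the degrees
    ``>= d_min`` (default ``d_min = 1``: the whole distribution). The
    estimate is clamped below at 1.5 (so beta stays <= 2); the clamp fires
    when the degrees carry no tail information (e.g. all equal to d_min).
    """
    d = np.asarray(degrees, dtype=float)
    if (d < 1).any():
        raise ValueError("degrees must be >= 1")
    d = d[d >= d_min]
    if d.size < 2:
        raise ValueError("need at least two degrees >= d_min to fit an exponent")
    log_sum = float(np.log(d / d_min).sum())
    if log_sum <= 0.0:
        warnings.warn("all degrees at d_min; exponent clamped", stacklevel=2)
        return PowerLawFit(LAMBDA_MIN, clamped=True)
    lam = 1.0 + d.size / log_sum
    if lam < LAMBDA_MIN:
        warnings.warn(f"fitted exponent {lam:.3f} below clamp {LAMBDA_MIN}", stacklevel=2)
        return PowerLawFit(LAMBDA_MIN, clamped=True)
    return PowerLawFit(lam)


def _component_masks(matrix: np.ndarray) -> list[np.ndarray]:
    """Connected components of the weighted-adjacency support, largest first
    (ties by smallest member index), restricted to non-isolated rows."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    support = matrix != 0.0
    active = support.any(axis=1)
    n_comp, labels = connected_components(csr_matrix(support), directed=False)
    comps = []
    for c in range(n_comp):
        mask = (labels == c) & active
        if mask.any():
            comps.append(mask)
    comps.sort(key=lambda m: (-int(m.sum()), int(np.argmax(m))))
    return comps


def graphlet_spectral_embedding(adj: GraphletAdjacency, dim: int = 2) -> CartesianEmbedding:
    """Laplacian-eigenmaps embedding of the normalized graphlet adjacency.

    Coordinates are the eigenvectors of ``L = I - A~_Gi`` for the ``dim``
    smallest nonzero eigenvalues, computed on the largest connected
    component of the graphlet-adjacency graph. Nodes outside that component
    (including nodes that touch the graphlet zero times) are dropped and
    reported in ``dropped``. Eigenvector signs are fixed so the first
    entry of magnitude > 1e-12 is positive.
    """
    if not adj.normalized:
        raise ValueError("spectral embedding requires the normalized graphlet adjacency")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    comps = _component_masks(adj.matrix)
    if not comps:
        raise ValueError("graphlet-adjacency graph has no edges; nothing to embed")
    mask = comps[0]
    idx = np.flatnonzero(mask)
    if idx.size < dim + 1:
        raise ValueError(
            f"largest graphlet-adjacency component has {idx.size} nodes; "
            f"need at least {dim + 1} for a {dim}-dimensional embedding"
        )
    sub = adj.matrix[np.ix_(idx, idx)]
    lap = np.eye(idx.size) - sub
    vals, vecs = np.linalg.eigh(lap)
    # a connected component contributes exactly one (numerically) zero
    # eigenvalue; the next `dim` carry the geometry
    order = np.argsort(vals, kind="stable")
    chosen = order[1 : dim + 1]
    coords = vecs[:, chosen]
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    nodes = tuple(adj.nodes[i] for i in idx)
    dropped = tuple(u for k, u in enumerate(adj.nodes) if not mask[k])
    return CartesianEmbedding(nodes, coords[:, :dim].copy(), dropped)


def angular_coordinates(cart: CartesianEmbedding) -> dict[str, float]:
    """Equidistant peripheral angles from a 2D embedding.

    The raw angle of each node is measured against the positive y-axis (the
    pole), compass-style; nodes are ranked by (raw angle, label) and the
    node of rank k among N embedded nodes receives the final angle
    ``2*pi*k/N``, i.e. the nodes are placed equidistantly on the disk
    periphery in raw-angle order. A node at the exact origin is assigned
    raw angle 0 (logged).
    """
    if len(cart.nodes) == 0:
        raise ValueError("empty embedding")
    if cart.coords.shape[1] != 2:
        raise ValueError("angular coordinates need a 2D embedding")
    raw = []
    for u, (x, y) in zip(cart.nodes, cart.coords):
        if x == 0.0 and y == 0.0:
            logger.info("node %s at embedding origin; pole angle 0 assigned", u)
            raw.append((0.0, u))
        else:
            raw.append((math.atan2(x, y) % (2.0 * math.pi), u))
    order = sorted(range(len(raw)), key=lambda i: raw[i])
    n = len(order)
    angles: dict[str, float] = {}
    for rank, i in enumerate(order):
        angles[cart.nodes[i]] = 2.0 * math.pi * rank / n
    return angles


def _rank(values: dict[str, float]) -> dict[str, int]:
    """1-based ranks, highest value first, ties broken by ascending label."""
    order = sorted(values, key=lambda u: (-values[u], u))
    return {u: r + 1 for r, u in enumerate(order)}


def radial_gracoal(node_counts: dict[str, float]) -> dict[str, float]:
    """GraCoal radius: ``rad_u = ln(r_u)`` with r_u the graphlet-count rank.

    The node touching the graphlet most often has rank 1 and sits at the
    disk centre (radius 0).
    """
    return {u: math.log(r) for u, r in _rank(node_counts).items()}


def radial_coalescent(degrees: dict[str, float], fit: PowerLawFit) -> dict[str, float]:
    """CE radius: ``rad_u = beta*ln(r_u) + (1-beta)*ln(N)``, degree-ranked."""
    n = len(degrees)
    beta = fit.beta
    log_n = math.log(n) if n > 0 else 0.0
    return {u: beta * math.log(r) + (1.0 - beta) * log_n for u, r in _rank(degrees).items()}


def _disk_from_parts(
    nodes_sorted: tuple[str, ...],
    angles: dict[str, float],
    radii: dict[str, float],
    dropped: tuple[str, ...],
) -> DiskEmbedding:
    ang = np.array([angles[u] for u in nodes_sorted])
    rad = np.array([radii[u] for u in nodes_sorted])
    return DiskEmbedding(nodes_sorted, ang, rad, dropped)


def _normalized_graphlet_adjacency(network: Network, graphlet_index: int):
    counts = count_graphlets(network)
    return normalize_adjacency(graphlet_adjacency(counts, graphlet_index)), counts


def gracoal_embed(network: Network, graphlet_index: int) -> DiskEmbedding:
    """Full GraCoal embedding of a network for one graphlet.

    Deterministic composition: exact graphlet counting, normalized graphlet
    adjacency, 2D spectral embedding of its largest component, equidistant
    angles, ``ln(rank)`` radii from the graphlet touch counts of the
    embedded nodes.
    """
    norm, counts = _normalized_graphlet_adjacency(network, graphlet_index)
    cart = graphlet_spectral_embedding(norm, dim=2)
    angles = angular_coordinates(cart)
    t_col = counts.node_counts[:, graphlet_index]
    count_of = {u: int(t_col[k]) for k, u in enumerate(counts.nodes)}
    radii = radial_gracoal({u: count_of[u] for u in cart.nodes})
    return _disk_from_parts(cart.nodes, angles, radii, cart.dropped)


def coalescent_embed(network: Network) -> DiskEmbedding:
    """Classical coalescent embedding (CE) baseline.

    Spectral (Laplacian eigenmaps) step on the standard adjacency, then the
    degree-ranked radius ``beta*ln(r) + (1-beta)*ln(N)`` with beta from the
    power-law fit of the degree distribution.
    """
    norm, _counts = _normalized_graphlet_adjacency(network, 0)
    cart = graphlet_spectral_embedding(norm, dim=2)
    angles = angular_coordinates(cart)
    deg = {u: float(network.degree(u)) for u in cart.nodes}
    fit = fit_power_law([max(1, int(d)) for d in deg.values()])
    radii = radial_coalescent(deg, fit)
    if any(r < 0 for r in radii.values()):
        # beta > 1 only happens at the exponent clamp, outside the power-law
        # regime the radius formula assumes; floor at the disk centre
        logger.info("negative CE radii floored at 0 (clamped exponent regime)")
        radii = {u: max(0.0, r) for u, r in radii.items()}
    return _disk_from_parts(cart.nodes, angles, radii, cart.dropped)


def spectral_embed(network: Network, graphlet_index: int = 0) -> CartesianEmbedding:
    """Bare Graphlet Spectral embedding (2D Cartesian), no disk mapping."""
    norm, _ = _normalized_graphlet_adjacency(network, graphlet_index)
    return graphlet_spectral_embedding(norm, dim=2)


def graspring_embed(
    network: Network,
    graphlet_index: int,
    init: CartesianEmbedding | None = None,
    iterations: int = 50,
) -> CartesianEmbedding:
    """GraSpring: force-directed layout with graphlet-weighted springs.

    A Fruchterman–Reingold loop in which the attraction along each edge of
    the graphlet-adjacency graph is multiplied by the normalized graphlet
    adjacency weight; repulsion is uniform. With a fixed iteration count,
    a linear cooling schedule and the (deterministic) spectral embedding as
    initialization, the layout is a pure function of its inputs. Zero
    iterations return the initial coordinates unchanged.
    """
    norm, _ = _normalized_graphlet_adjacency(network, graphlet_index)
    if init is None:
        init = graphlet_spectral_embedding(norm, dim=2)
    else:
        missing = [u for u in graphlet_spectral_embedding(norm, dim=2).nodes if u not in set(init.nodes)]
        if missing:
            raise ValueError(f"init is missing embedded nodes: {missing[:5]}")
    node_pos = init.as_dict()
    nodes = init.nodes
    pos = np.array([node_pos[u] for u in nodes], dtype=float)
    if iterations == 0:
        return CartesianEmbedding(nodes, pos, init.dropped)
    full_idx = {u: k for k, u in enumerate(norm.nodes)}
    sel = np.array([full_idx[u] for u in nodes])
    w = norm.matrix[np.ix_(sel, sel)]
    n = len(nodes)
    k = 1.0 / math.sqrt(n)
    t = 0.1
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.clip(dist, 1e-9, None)
        # uniform repulsion k^2/d, weighted attraction w*d^2/k
        coef = (k * k) / (dist * dist) - w * dist / k
        disp = (delta * coef[:, :, None]).sum(axis=1)
        length = np.clip(np.linalg.norm(disp, axis=1), 1e-12, None)
        pos = pos + disp / length[:, None] * np.minimum(length, t)[:, None]
        t -= dt
    return CartesianEmbedding(nodes, pos, init.dropped)
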