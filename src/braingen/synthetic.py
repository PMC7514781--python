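"""Synthetic spatially embedded connectomes and forged stage pairs.

The generator emulates the inputs the pipeline expects from a real study:
90 region centroids inside a brain-sized ellipsoid, a connected
thresholded-correlation-like binary network at a requested density with
distance-dependent wiring and elevated clustering, a forged
initial/target stage pair produced by the generative model itself (so the
generating parameters are known ground truth for recovery tests), and
region time series whose sample correlation structure reflects the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connection import ModelParams, euclidean_distance_matrix
from .evolution import EvolutionQuota, EvolutionTrace, evolve
from .graph_core import BrainGraph, CoordinateTable

# semi-axes in mm of the sampling ellipsoid (~140 x 170 x 120 mm extent,
# the rough bounding box of an adult cerebrum in MNI space)
ELLIPSOID_SEMI_AXES = (70.0, 85.0, 60.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic connectome generator.

    The generator mimics a thresholded group-average correlation matrix:
    inter-regional coupling decays with distance over ``decay_length`` (mm),
    ``community_strength`` adds block structure over ``n_communities``
    spatially contiguous modules, ``factor_strength`` adds a rank-one
    global-signal factor with heterogeneous loadings (producing hub-like
    cores), and ``noise_scale`` perturbs every pair.  ``rewiring_fraction``
    optionally moves that share of edges into triangle-closing positions
    after thresholding for extra clustering.  Defaults are calibrated so a
    90-node, density-0.15 network reproduces the topological profile
    reported for thresholded resting-state connectomes (C ≈ 0.6, L ≈ 2,
    T ≈ 0.5, M ≈ 0.3).
    """

    seed: int
    n_nodes: int = 90
    density: float = 0.15
    decay_length: float = 40.0
    rewiring_fraction: float = 0.0
    community_strength: float = 0.1
    n_communities: int = 5
    factor_strength: float = 1.0
    noise_scale: float = 0.08

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("need at least 10 nodes")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.decay_length <= 0:
            raise ValueError("decay length must be positive")
        if not 0.0 <= self.rewiring_fraction <= 1.0:
            raise ValueError("rewiring fraction must lie in [0, 1]")
        if self.n_communities < 1:
            raise ValueError("need at least one community")
        for label in ("community_strength", "factor_strength", "noise_scale"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be nonnegative")


@dataclass(frozen=True)
class StagePair:
    """A forged initial/target pair with its generative ground truth."""

    initial: BrainGraph
    target: BrainGraph
    coords: CoordinateTable
    true_params: ModelParams
    quota: EvolutionQuota
    evolution_seed: int
    trace: EvolutionTrace


def generate_coordinates(spec: SyntheticSpec) -> CoordinateTable:
    """Sample n distinct points uniformly inside the brain-sized ellipsoid."""
    rng = np.random.default_rng(spec.seed)
    semi = np.asarray(ELLIPSOID_SEMI_AXES)
    points = np.empty((0, 3))
    while len(points) < spec.n_nodes:
        draw = rng.uniform(-1.0, 1.0, size=(4 * spec.n_nodes, 3))
        inside = (draw ** 2).sum(axis=1) <= 1.0
        points = np.vstack([points, draw[inside] * semi])
    points = points[: spec.n_nodes]
    return CoordinateTable(
        {i + 1: tuple(float(x) for x in points[i]) for i in range(spec.n_nodes)}
    )


def synthetic_coupling_matrix(spec: SyntheticSpec, coords: CoordinateTable) -> np.ndarray:
    """Model correlation-like coupling strengths between all region pairs.

    coupling = factor·u_i·u_j + exp(−d/decay) + community bonus + noise,
    with positive heterogeneous factor loadings u (hub cores), spatially
    contiguous communities from a seeded k-means of the centroids, and
    symmetric Gaussian pair noise.  Zero diagonal.
    """
    from scipy.cluster.vq import kmeans2

    n = spec.n_nodes
    order = coords.node_ids
    if len(order) != n:
        raise ValueError("coordinate table does not match node count")
    rng = np.random.default_rng(spec.seed + 29)
    d = euclidean_distance_matrix(coords).values
    pts = coords.array(order)
    _, labels = kmeans2(pts, min(spec.n_communities, n), seed=int(rng.integers(2 ** 31)),
                        minit="++")
    same_block = (labels[:, None] == labels[None, :]).astype(float)
    loadings = rng.uniform(0.0, 1.0, size=n)
    noise = rng.standard_normal((n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)
    coupling = (
        spec.factor_strength * np.outer(loadings, loadings)
        + np.exp(-d / spec.decay_length)
        + spec.community_strength * same_block
        + spec.noise_scale * noise
    )
    np.fill_diagonal(coupling, 0.0)
    return coupling


def generate_initial_network(spec: SyntheticSpec, coords: CoordinateTable) -> BrainGraph:
    """Connected graph at the requested density, emulating a thresholded
    group-average correlation network.

    The synthetic coupling matrix is thresholded at the density-matched
    cutoff (exactly ``round(density · n(n−1)/2)`` edges).  If thresholding
    leaves several components, the strongest coupling crossing each
    component boundary is swapped in for the weakest removable retained
    edge, so the result is connected at the same edge count.  An optional
    triadic-closure pass then rewires ``rewiring_fraction`` of the edges
    into triangle-closing positions.
    """
    n = spec.n_nodes
    order = coords.node_ids
    m_target = int(round(spec.density * n * (n - 1) / 2))
    if m_target < n - 1:
        raise ValueError(
            f"density {spec.density} gives {m_target} edges, below the "
            f"connectivity minimum of {n - 1}"
        )
    rng = np.random.default_rng(spec.seed + 17)
    coupling = synthetic_coupling_matrix(spec, coords)
    iu, ju = np.triu_indices(n, k=1)
    vals = coupling[iu, ju]
    keep = np.argsort(vals)[-m_target:]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a[ju[keep], iu[keep]] = 1
    g = BrainGraph.from_adjacency(a, order)
    _repair_connectivity(g, coupling, order)
    _triadic_rewiring(g, coupling, order, spec.rewiring_fraction, rng)
    assert g.edge_count() == m_target and g.is_connected()
    return g


def _repair_connectivity(g: BrainGraph, coupling: np.ndarray, order) -> None:
    """Swap weakest retained edges for strongest component-bridging pairs."""
    index = {u: i for i, u in enumerate(order)}
    while True:
        components = _components(g)
        if len(components) == 1:
            return
        # strongest absent pair crossing between two components
        best, best_val = None, -np.inf
        for ci in range(len(components)):
            for cj in range(ci + 1, len(components)):
                for u in components[ci]:
                    for v in components[cj]:
                        val = coupling[index[u], index[v]]
                        if val > best_val:
                            best, best_val = (u, v), val
        # weakest droppable edge: removal must not split a component further
        n_before = len(components)
        for u, v in sorted(g.edges(), key=lambda e: coupling[index[e[0]], index[e[1]]]):
            if g.degree(u) <= 1 or g.degree(v) <= 1:
                continue
            g.remove_edge(u, v)
            if len(_components(g)) == n_before:
                break
            g.add_edge(u, v)
        else:
            raise RuntimeError("cannot repair connectivity at this density")
        g.add_edge(*best)


def _components(g: BrainGraph) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in g.node_ids:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in g.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def _triadic_rewiring(g, coupling, order, fraction: float, rng) -> None:
    """Move a fraction of weakest edges into triangle-closing positions."""
    if fraction <= 0:
        return
    index = {u: i for i, u in enumerate(order)}
    n_rewire = int(round(fraction * g.edge_count()))
    for _ in range(n_rewire):
        closure = _open_triangle(g, rng, order)
        if closure is None:
            break
        for u, v in sorted(g.edges(), key=lambda e: coupling[index[e[0]], index[e[1]]]):
            if g.degree(u) <= 1 or g.degree(v) <= 1 or (u, v) == closure:
                continue
            g.remove_edge(u, v)
            if g.is_connected():
                g.add_edge(*closure)
                break
            g.add_edge(u, v)
        else:
            break


def _open_triangle(g, rng, order, tries: int = 50):
    """A random unconnected neighbor pair (m, n) of a random node."""
    n = len(order)
    for _ in range(tries):
        z = order[rng.integers(n)]
        nbrs = sorted(g.neighbors(z))
        if len(nbrs) < 2:
            continue
        m, nn = rng.choice(len(nbrs), size=2, replace=False)
        u, v = nbrs[m], nbrs[nn]
        if not g.has_edge(u, v):
            return (u, v) if u < v else (v, u)
    return None


def generate_stage_pair(
    spec: SyntheticSpec,
    params: ModelParams | None = None,
    quota: EvolutionQuota | None = None,
) -> StagePair:
    """Forge an initial network and a target evolved from it by known params.

    Defaults mimic a degenerating stage transition: β > α (net connection
    loss) and the mutual-information model with γ = 0.2, η = 1.8.  The
    evolution seed is derived from the spec seed; if an evolution run
    disconnects the target (which would leave the six-metric comparison
    undefined), further derived seeds are tried so every returned target is
    a valid, connected stage network.
    """
    import warnings

    if params is None:
        params = ModelParams(index_name="MI", gamma=0.2, eta=1.8)
    if quota is None:
        quota = EvolutionQuota(additions=20, deletions=40)
    coords = generate_coordinates(spec)
    initial = generate_initial_network(spec, coords)
    distances = euclidean_distance_matrix(coords)
    for attempt in range(20):
        evolution_seed = spec.seed + 1 + 1009 * attempt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            target, trace = evolve(initial, params, distances, quota, seed=evolution_seed)
        if target.is_connected():
            return StagePair(initial, target, coords, params, quota, evolution_seed, trace)
    raise RuntimeError(
        "could not forge a connected target in 20 attempts; "
        "the quota is too destructive for this network"
    )


_HOP_DECAY = 0.3  # population correlation per graph hop


def generate_timeseries(
    g: BrainGraph, t_length: int, noise: float = 0.3, seed: int = 0
) -> dict[int, np.ndarray]:
    """Gaussian region time series whose correlations reflect the graph.

    The population correlation between two regions decays geometrically
    with their shortest-path distance in g (0.3 per hop), so adjacent
    regions are markedly more correlated than any non-adjacent pair.  The
    matrix is made positive definite by a uniform diagonal inflation, which
    rescales all correlations equally and therefore never reorders them;
    ``noise`` adds further independent variance, shrinking correlations
    toward zero.  At t_length = 500 and default noise, thresholding the
    sample correlation at the density-matched θ recovers ≥ 90% of edges.
    """
    if t_length < 50:
        raise ValueError("need at least 50 time points")
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    from .metrics import _shortest_paths

    rng = np.random.default_rng(seed)
    a = g.to_adjacency().astype(float)
    n = a.shape[0]
    hops = _shortest_paths(a)
    with np.errstate(invalid="ignore"):
        base = np.where(np.isfinite(hops), _HOP_DECAY ** hops, 0.0)
    np.fill_diagonal(base, 1.0)
    lam_min = float(np.linalg.eigvalsh(base)[0])
    inflation = max(0.0, -lam_min + 0.05)
    cov = base + (inflation + noise ** 2) * np.eye(n)
    chol = np.linalg.cholesky(cov)
    data = rng.standard_normal(size=(t_length, n)) @ chol.T
    return {u: data[:, i].copy() for i, u in enumerate(g.node_ids)}
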