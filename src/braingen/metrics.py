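"""Graph-level network properties and the similarity index SI.

Six properties summarize each network: mean local clustering C, local
efficiency Eloc, modularity M, characteristic path length L, global
efficiency Eglob and transitivity T.  A synthetic network is compared to a
target through the relative error ξ of each property, and the fit quality is

    SI = 1 / (ξC + ξEloc + ξM + ξL + ξEglob + ξT),

so larger SI means a closer match, with a perfect fit reported as +inf.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import BrainGraph

METRIC_NAMES = ("C", "Eloc", "M", "L", "Eglob", "T")


@dataclass(frozen=True)
class MetricVector:
    C: float
    Eloc: float
    M: float
    L: float
    Eglob: float
    T: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FitErrors:
    """Relative errors ξ of the six properties, plus the derived SI."""

    xi_C: float
    xi_Eloc: float
    xi_M: float
    xi_L: float
    xi_Eglob: float
    xi_T: float

    @property
    def SI(self) -> float:
        return similarity_index(
            [self.xi_C, self.xi_Eloc, self.xi_M, self.xi_L, self.xi_Eglob, self.xi_T]
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "xi_C": self.xi_C,
            "xi_Eloc": self.xi_Eloc,
            "xi_M": self.xi_M,
            "xi_L": self.xi_L,
            "xi_Eglob": self.xi_Eglob,
            "xi_T": self.xi_T,
        }
        d["SI"] = self.SI
        return d


def _shortest_paths(a: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf for unreachable)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def _efficiency_from_adjacency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    sp = _shortest_paths(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(g: BrainGraph) -> float:
    """Mean local clustering; degree-<2 nodes contribute 0."""
    a = g.to_adjacency().astype(float)
    deg = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0  # closed triangles at each node
    denom = deg * (deg - 1.0) / 2.0
    local = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return float(local.mean()) if len(local) else 0.0


def transitivity(g: BrainGraph) -> float:
    """Global ratio 3 × triangles / connected triples."""
    a = g.to_adjacency().astype(float)
    deg = a.sum(axis=1)
    closed = ((a @ a) * a).sum()  # = 6 x triangle count
    triples = (deg * (deg - 1.0)).sum()  # = 2 x connected-triple count
    return float(closed / triples) if triples > 0 else 0.0


def characteristic_path_length(g: BrainGraph) -> float:
    """Mean shortest-path length over all node pairs; errors if disconnected."""
    if g.n_nodes < 2:
        raise ValueError("path length undefined for graphs with < 2 nodes")
    sp = _shortest_paths(g.to_adjacency())
    off = ~np.eye(g.n_nodes, dtype=bool)
    if not np.isfinite(sp[off]).all():
        raise ValueError("characteristic path length undefined for disconnected graphs")
    return float(sp[off].mean())


def global_efficiency(g: BrainGraph) -> float:
    """Mean inverse shortest-path length over pairs (0 for unreachable pairs)."""
    return _efficiency_from_adjacency(g.to_adjacency())


def local_efficiency(g: BrainGraph) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph."""
    a = g.to_adjacency()
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) >= 2:
            total += _efficiency_from_adjacency(a[np.ix_(nbrs, nbrs)])
    return total / n


def modularity(g: BrainGraph, seed: int = 0) -> float:
    """Newman modularity Q of a seeded Louvain partition (deterministic per seed)."""
    if g.edge_count() == 0:
        raise ValueError("modularity undefined for an empty edge set")
    nxg = g.to_networkx()
    partition = nx.community.louvain_communities(nxg, seed=seed)
    return float(nx.community.modularity(nxg, partition))


def modularity_exhaustive(g: BrainGraph) -> float:
    """Maximum modularity over all partitions; exact oracle for <= 12 nodes."""
    if g.n_nodes > 12:
        raise ValueError("exhaustive partition search is limited to 12 nodes")
    if g.edge_count() == 0:
        raise ValueError("modularity undefined for an empty edge set")
    nxg = g.to_networkx()
    nodes = list(g.node_ids)

    def partitions(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
            yield [[head]] + part

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(nxg, [set(block) for block in part])
        best = max(best, q)
    return float(best)


def cumulative_degree_distribution(g: BrainGraph) -> pd.DataFrame:
    """Complementary cumulative degree distribution P(K >= k).

    One row per observed degree value k, non-increasing in k, with
    P(K >= min degree) = 1.
    """
    degrees = np.array([g.degree(u) for u in g.node_ids])
    ks = np.unique(degrees)
    probs = [(degrees >= k).mean() for k in ks]
    return pd.DataFrame({"degree": ks, "cumulative_probability": probs})


def relative_error(x_syn: float, x_target: float) -> float:
    """|x_syn − x_target| / |x_target|; the target value must be nonzero."""
    if x_target == 0:
        raise ValueError("relative error undefined for a zero target value")
    return abs(x_syn - x_target) / abs(x_target)


def similarity_index(errors) -> float:
    """SI = 1 / Σξ over the six relative errors; +inf when all errors are 0."""
    errors = list(errors)
    if len(errors) != 6:
        raise ValueError(f"expected six relative errors, got {len(errors)}")
    if any(e < 0 for e in errors):
        raise ValueError("relative errors must be nonnegative")
    total = float(sum(errors))
    return float("inf") if total == 0.0 else 1.0 / total


def metric_vector(g: BrainGraph, seed: int = 0) -> MetricVector:
    """All six properties in one call; modularity uses the given seed."""
    return MetricVector(
        C=clustering_coefficient(g),
        Eloc=local_efficiency(g),
        M=modularity(g, seed=seed),
        L=characteristic_path_length(g),
        Eglob=global_efficiency(g),
        T=transitivity(g),
    )


def fit_errors(synthetic: MetricVector, target: MetricVector) -> FitErrors:
    """Component-wise relative errors of a synthetic network against a target."""
    return FitErrors(
        xi_C=relative_error(synthetic.C, target.C),
        xi_Eloc=relative_error(synthetic.Eloc, target.Eloc),
        xi_M=relative_error(synthetic.M, target.M),
        xi_L=relative_error(synthetic.L, target.L),
        xi_Eglob=relative_error(synthetic.Eglob, target.Eglob),
        xi_T=relative_error(synthetic.T, target.T),
    )


def write_metrics(mv: MetricVector, path: str | Path) -> None:
    pd.DataFrame([mv.as_dict()]).to_csv(path, index=False)


def write_degree_distribution(g: BrainGraph, path: str | Path) -> None:
    cumulative_degree_distribution(g).to_csv(path, sep="\t", index=False)
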