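"""Binary undirected graphs over integer region ids.

The package models brain networks as simple, undirected, unweighted graphs
whose nodes are parcellation region identifiers (e.g. 1..90 for an AAL-style
atlas, but any positive integers are accepted).  The node set is fixed at
construction; only edges change during network evolution, which lets every
topological quantity assume a constant ``|V|``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class UnknownNodeError(KeyError):
    """Raised when an operation names a node id not present in the graph."""

    def __init__(self, node: int) -> None:
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError repr-quotes its arg; we want a message
        return f"unknown node id: {self.node}"


def _canonical(u: int, v: int) -> tuple[int, int]:
    """Canonical unordered-pair form (min, max)."""
    return (u, v) if u < v else (v, u)


class BrainGraph:
    """Simple undirected binary graph with a fixed node set.

    Parameters
    ----------
    node_ids:
        Iterable of positive integers; order is preserved and defines the
        row/column order of any matrix representation.
    edges:
        Optional iterable of node-id pairs.  Pairs are stored unordered;
        self-loops are rejected.
    """

    __slots__ = ("_order", "_adj", "_n_edges")

    def __init__(self, node_ids: Iterable[int], edges: Iterable[tuple[int, int]] = ()) -> None:
        order = [int(u) for u in node_ids]
        if len(order) != len(set(order)):
            raise ValueError("duplicate node ids")
        if any(u <= 0 for u in order):
            raise ValueError("node ids must be positive integers")
        self._order: tuple[int, ...] = tuple(order)
        self._adj: dict[int, set[int]] = {u: set() for u in order}
        self._n_edges = 0
        for u, v in edges:
            self.add_edge(int(u), int(v))

    # -- basic accessors ---------------------------------------------------

    @property
    def node_ids(self) -> tuple[int, ...]:
        return self._order

    @property
    def n_nodes(self) -> int:
        return len(self._order)

    def __contains__(self, u: int) -> bool:
        return u in self._adj

    def _check(self, u: int) -> None:
        if u not in self._adj:
            raise UnknownNodeError(u)

    def neighbors(self, u: int) -> set[int]:
        """Neighbor set Γ(u); never contains u itself."""
        self._check(u)
        return set(self._adj[u])

    def degree(self, u: int) -> int:
        """|Γ(u)|, the connection number of node u."""
        self._check(u)
        return len(self._adj[u])

    def edge_count(self) -> int:
        """|E|, the number of existing connections."""
        return self._n_edges

    def has_edge(self, u: int, v: int) -> bool:
        self._check(u)
        self._check(v)
        return v in self._adj[u]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Iterate edges as canonical (min, max) pairs."""
        for u in self._order:
            for v in self._adj[u]:
                if u < v:
                    yield (u, v)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges())

    def neighborhood_edge_count(self, z: int) -> int:
        """Number of edges with both endpoints in Γ(z) (the |Ez| of the
        conditional link probability)."""
        self._check(z)
        nbrs = self._adj[z]
        count = 0
        for v in nbrs:
            count += len(self._adj[v] & nbrs)
        return count // 2

    # -- edits -------------------------------------------------------------

    def add_edge(self, u: int, v: int) -> None:
        self._check(u)
        self._check(v)
        if u == v:
            raise ValueError(f"self-loop on node {u} not allowed")
        if v not in self._adj[u]:
            self._adj[u].add(v)
            self._adj[v].add(u)
            self._n_edges += 1

    def remove_edge(self, u: int, v: int) -> None:
        self._check(u)
        self._check(v)
        if v not in self._adj[u]:
            raise ValueError(f"edge ({u}, {v}) not present")
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._n_edges -= 1

    def copy(self) -> "BrainGraph":
        g = BrainGraph(self._order)
        g._adj = {u: set(nbrs) for u, nbrs in self._adj.items()}
        g._n_edges = self._n_edges
        return g

    # -- global structure --------------------------------------------------

    def is_connected(self) -> bool:
        """True iff a single component spans all nodes (BFS)."""
        if self.n_nodes == 0:
            return True
        start = self._order[0]
        seen = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_nodes

    # -- conversions -------------------------------------------------------

    def to_adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in node_ids order."""
        index = {u: i for i, u in enumerate(self._order)}
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for u, v in self.edges():
            i, j = index[u], index[v]
            a[i, j] = a[j, i] = 1
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._order)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_adjacency(cls, a: np.ndarray, node_ids: Iterable[int]) -> "BrainGraph":
        a = np.asarray(a)
        order = list(node_ids)
        if a.shape != (len(order), len(order)):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency matrix must have zero diagonal")
        ii, jj = np.nonzero(np.triu(a, 1))
        return cls(order, [(order[i], order[j]) for i, j in zip(ii, jj)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainGraph):
            return NotImplemented
        return self._order == other._order and self._adj == other._adj

    def __repr__(self) -> str:
        return f"BrainGraph(n_nodes={self.n_nodes}, n_edges={self._n_edges})"


@dataclass(frozen=True)
class CoordinateTable:
    """Node id → (x, y, z) coordinates in millimetres (MNI-style space)."""

    positions: Mapping[int, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, p in self.positions.items():
            if len(p) != 3 or not all(np.isfinite(p)):
                raise ValueError(f"node {u}: coordinates must be a finite (x, y, z) triple")

    @property
    def node_ids(self) -> tuple[int, ...]:
        return tuple(self.positions)

    def array(self, order: Iterable[int]) -> np.ndarray:
        """(n, 3) coordinate array in the given node order."""
        rows = []
        for u in order:
            if u not in self.positions:
                raise UnknownNodeError(u)
            rows.append(self.positions[u])
        return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# File formats


def read_edge_list(path: str | Path, node_ids: Iterable[int] | None = None) -> BrainGraph:
    """Read a two-column TSV of 1-based node ids, one edge per line.

    A single header line is tolerated and auto-detected (non-integer first
    row).  If *node_ids* is omitted the node set is the union of endpoint ids.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: non-integer node id") from None
            pairs.append((u, v))
    if node_ids is None:
        node_ids = sorted({u for p in pairs for u in p})
    return BrainGraph(node_ids, pairs)


def write_edge_list(g: BrainGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_adjacency(path: str | Path) -> BrainGraph:
    """Read a square 0/1 adjacency TSV with node-id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    node_ids = [int(c) for c in df.columns]
    if [int(r) for r in df.index] != node_ids:
        raise ValueError(f"{path}: row and column node ids differ")
    a = df.to_numpy()
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{path}: adjacency entries must be 0 or 1")
    return BrainGraph.from_adjacency(a.astype(np.int8), node_ids)


def write_adjacency(g: BrainGraph, path: str | Path) -> None:
    df = pd.DataFrame(g.to_adjacency(), index=g.node_ids, columns=g.node_ids)
    df.to_csv(path, sep="\t")


def read_coordinates(path: str | Path) -> CoordinateTable:
    """Read a coordinate CSV with columns node_id,x,y,z (mm)."""
    df = pd.read_csv(path)
    required = {"node_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns node_id,x,y,z")
    positions = {
        int(row.node_id): (float(row.x), float(row.y), float(row.z))
        for row in df.itertuples()
    }
    if len(positions) != len(df):
        raise ValueError(f"{path}: duplicate node ids")
    return CoordinateTable(positions)


def write_coordinates(coords: CoordinateTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(u, *coords.positions[u]) for u in coords.node_ids],
        columns=["node_id", "x", "y", "z"],
    )
    df.to_csv(path, index=False)


def write_graphml(g: BrainGraph, path: str | Path, coords: CoordinateTable | None = None) -> None:
    """GraphML export for external visualization tools."""
    import networkx as nx

    nxg = g.to_networkx()
    if coords is not None:
        for u in g.node_ids:
            x, y, z = coords.positions[u]
            nxg.nodes[u].update(x=x, y=y, z=z)
    nx.write_graphml(nxg, str(path))
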