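"""Add/delete evolution of a connectome toward a target stage.

Starting from an initial binary network, the engine performs exactly α edge
additions and β edge deletions.  Before every single event the similarity
and connection-probability matrices are recomputed on the current graph;
the absent pair with the largest P is connected on an "add" event and the
present pair with the smallest P is cut on a "delete" event.  A degree
guard walks down the deletion ranking past any pair in which either
endpoint has only one remaining connection, so no node is ever isolated.

The order in which the two quotas are spent is randomized: each event is an
addition with probability remaining_α / (remaining_α + remaining_β).  With a
fixed seed the whole trace is reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connection import DistanceMatrix, ModelParams, connection_probability_matrix, rank_candidates
from .graph_core import BrainGraph
from .similarity import similarity_matrix


class InfeasibleQuotaError(ValueError):
    """Raised when a quota cannot be met before any mutation happens."""


@dataclass(frozen=True)
class EvolutionQuota:
    """Numbers of connections to add (α) and delete (β)."""

    additions: int
    deletions: int

    def __post_init__(self) -> None:
        if self.additions < 0 or self.deletions < 0:
            raise ValueError("quotas must be nonnegative")


@dataclass
class EvolutionTrace:
    """Ordered record of edge events: (step, action, u, v)."""

    events: list[tuple[int, str, int, int]] = field(default_factory=list)
    seed: int | None = None
    final_connected: bool | None = None

    @property
    def n_additions(self) -> int:
        return sum(1 for e in self.events if e[1] == "add")

    @property
    def n_deletions(self) -> int:
        return sum(1 for e in self.events if e[1] == "delete")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.events, columns=["step", "action", "node_u", "node_v"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EvolutionTrace":
        df = pd.read_csv(path)
        events = [
            (int(r.step), str(r.action), int(r.node_u), int(r.node_v)) for r in df.itertuples()
        ]
        return cls(events)


def edge_change_counts(initial: BrainGraph, target: BrainGraph) -> EvolutionQuota:
    """Quota (α, β) = (edges only in target, edges only in initial)."""
    if set(initial.node_ids) != set(target.node_ids):
        raise ValueError("initial and target graphs have different node sets")
    e_init = initial.edge_set()
    e_target = target.edge_set()
    return EvolutionQuota(additions=len(e_target - e_init), deletions=len(e_init - e_target))


def _check_feasible(initial: BrainGraph, quota: EvolutionQuota) -> None:
    n = initial.n_nodes
    max_edges = n * (n - 1) // 2
    final = initial.edge_count() + quota.additions - quota.deletions
    if final < 0 or final > max_edges:
        raise InfeasibleQuotaError(
            f"final edge count {final} outside [0, {max_edges}] for {n} nodes"
        )
    if quota.deletions > 0 and final < (n + 1) // 2:
        raise InfeasibleQuotaError(
            f"final edge count {final} cannot keep all {n} node degrees >= 1"
        )


def evolve(
    initial: BrainGraph,
    params: ModelParams,
    distances: DistanceMatrix | None,
    quota: EvolutionQuota,
    seed: int,
    strict: bool = False,
) -> tuple[BrainGraph, EvolutionTrace]:
    """Run the add/delete evolution and return (final graph, trace).

    ``strict=True`` forbids re-adding a previously deleted pair and
    re-deleting a previously added one, so the final symmetric difference
    from the initial graph is exactly α + β pairs.  ``distances`` may be
    None only for the RANDOM model or when η = 0.
    """
    _check_feasible(initial, quota)
    if params.index_name != "RANDOM" and params.eta > 0 and distances is None:
        raise ValueError("distance matrix required when η > 0")
    if not initial.is_connected():
        warnings.warn("initial graph is not connected", stacklevel=2)
    rng = np.random.default_rng(seed)
    g = initial.copy()
    trace = EvolutionTrace(seed=seed)
    remaining_add, remaining_del = quota.additions, quota.deletions
    added: set[tuple[int, int]] = set()
    deleted: set[tuple[int, int]] = set()
    step = 0
    while remaining_add + remaining_del > 0:
        p_add = remaining_add / (remaining_add + remaining_del)
        do_add = rng.random() < p_add
        if params.index_name == "RANDOM":
            pair = _random_event_pair(g, rng, do_add, added if strict else None,
                                      deleted if strict else None)
        else:
            s = similarity_matrix(g, params.index_name)
            p = connection_probability_matrix(g, s, distances, params)
            additions, deletions = rank_candidates(g, p, distances)
            pair = _ranked_event_pair(g, do_add, additions, deletions,
                                      added if strict else None, deleted if strict else None)
        if pair is None:
            raise RuntimeError(
                f"no eligible pair for {'addition' if do_add else 'deletion'} after "
                f"{trace.n_additions} additions and {trace.n_deletions} deletions"
            )
        u, v = pair
        if do_add:
            g.add_edge(u, v)
            added.add(pair)
            remaining_add -= 1
            trace.events.append((step, "add", u, v))
        else:
            g.remove_edge(u, v)
            deleted.add(pair)
            remaining_del -= 1
            trace.events.append((step, "delete", u, v))
        step += 1
    trace.final_connected = g.is_connected()
    if not trace.final_connected:
        warnings.warn("evolved graph is not globally connected", stacklevel=2)
    return g, trace


def _ranked_event_pair(g, do_add, additions, deletions, forbidden_add, forbidden_del):
    if do_add:
        for pair in additions:
            if forbidden_add is not None and pair in forbidden_add:
                continue
            return pair
        return None
    for pair in deletions:
        u, v = pair
        if g.degree(u) <= 1 or g.degree(v) <= 1:
            continue  # each node must keep a connection
        if forbidden_del is not None and pair in forbidden_del:
            continue
        return pair
    return None


def _random_event_pair(g, rng, do_add, forbidden_add, forbidden_del):
    order = g.node_ids
    candidates = []
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if do_add and not g.has_edge(u, v):
                if forbidden_add is None or (u, v) not in forbidden_add:
                    candidates.append((u, v))
            elif not do_add and g.has_edge(u, v):
                if g.degree(u) > 1 and g.degree(v) > 1:
                    if forbidden_del is None or (u, v) not in forbidden_del:
                        candidates.append((u, v))
    if not candidates:
        return None
    return candidates[rng.integers(len(candidates))]


def trace_checkpoints(
    initial: BrainGraph,
    trace: EvolutionTrace,
    every_k: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Replay a trace and tabulate metrics after every k-th deletion.

    Returns a DataFrame with columns deleted_count, C, Eloc, M, L, Eglob, T.
    Row 0 describes the initial graph; a final row is always included even
    when the total deletion count is not a multiple of ``every_k``.
    """
    from .metrics import metric_vector

    if every_k <= 0:
        raise ValueError("every_k must be positive")
    g = initial.copy()
    rows = []

    def record(deleted: int) -> None:
        mv = metric_vector(g, seed=seed)
        rows.append((deleted, mv.C, mv.Eloc, mv.M, mv.L, mv.Eglob, mv.T))

    record(0)
    deleted = 0
    for _, action, u, v in trace.events:
        if action == "add":
            if g.has_edge(u, v):
                raise ValueError(f"trace not replayable: edge ({u},{v}) already present")
            g.add_edge(u, v)
        elif action == "delete":
            if not g.has_edge(u, v):
                raise ValueError(f"trace not replayable: edge ({u},{v}) absent")
            g.remove_edge(u, v)
            deleted += 1
            if deleted % every_k == 0:
                record(deleted)
        else:
            raise ValueError(f"unknown trace action {action!r}")
    if not rows or rows[-1][0] != deleted:
        record(deleted)
    return pd.DataFrame(rows, columns=["deleted_count", "C", "Eloc", "M", "L", "Eglob", "T"])
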