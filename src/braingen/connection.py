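"""Distance-penalized connection probabilities and candidate rankings.

A candidate pair (u, v) is scored P(u, v) = S(u, v)^γ · d(u, v)^(−η), where
S is a topological similarity index, d the Euclidean inter-region distance
in millimetres, γ ≥ 0 the similarity exponent (printed as λ in result
tables) and η ≥ 0 the distance-penalty exponent.  MI scores are
log-probabilities (≤ 0 or either sign), so they are exponentiated back to
the probability scale before the power law is applied:
P = exp(S_MI)^γ · d^(−η) = p(L¹|ω)^γ · d^(−η), which keeps the power-law
form with a positive base and preserves the score ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .graph_core import BrainGraph, CoordinateTable
from .similarity import INDEX_NAMES, SimilarityMatrix

MODEL_NAMES = INDEX_NAMES + ("RANDOM",)


@dataclass(frozen=True)
class ModelParams:
    """Generative-model parameters: similarity index and exponents (γ, η)."""

    index_name: str = "MI"
    gamma: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        name = self.index_name.upper()
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown index {self.index_name!r}; choose from {MODEL_NAMES}")
        object.__setattr__(self, "index_name", name)
        for label, value in (("gamma", self.gamma), ("eta", self.eta)):
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{label} must be finite and nonnegative, got {value}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise Euclidean distances in mm; symmetric with zero diagonal."""

    node_ids: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match node count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (off <= 0).any():
            raise ValueError("off-diagonal distances must be strictly positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_ids", tuple(int(u) for u in self.node_ids))


def euclidean_distance_matrix(coords: CoordinateTable) -> DistanceMatrix:
    """Straight-line distances between all region centroids."""
    order = coords.node_ids
    pts = coords.array(order)
    d = squareform(pdist(pts))
    n = len(order)
    off = d[~np.eye(n, dtype=bool)]
    if off.size and (off <= 0).any():
        raise ValueError("duplicate coordinates yield zero distance")
    return DistanceMatrix(order, d)


def connection_probability_matrix(
    g: BrainGraph,
    s: SimilarityMatrix,
    d: DistanceMatrix,
    params: ModelParams,
) -> np.ndarray:
    """P(u, v) = S(u, v)^γ · d(u, v)^(−η) over all pairs, in node_ids order.

    MI scores are log-probabilities and are positivized by exponentiation,
    P = exp(S)^γ · d^(−η); pairs with S = −inf (an isolated endpoint) get
    base 0 and rank last.  Pairs with S = 0 under a nonnegative index keep
    P = 0 regardless of γ (including γ = 0), so zero-similarity pairs
    always rank below positive-similarity ones.
    """
    if not (g.node_ids == s.node_ids == d.node_ids):
        raise ValueError("graph, similarity and distance node orders differ")
    if params.index_name == "RANDOM":
        raise ValueError("RANDOM model has no probability matrix; pairs are drawn uniformly")
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    scores = s.scores.astype(float).copy()
    if params.index_name == "MI":
        with np.errstate(over="ignore"):
            scores = np.exp(scores)  # back to the probability scale; -inf -> 0
    if params.eta > 0 and (d.values[off] <= 0).any():
        raise ValueError("zero distance with η > 0 is undefined")
    positive = scores > 0
    p = np.zeros_like(scores)
    with np.errstate(divide="ignore"):
        dist_term = np.where(off, d.values, 1.0) ** (-params.eta)
    p[positive] = scores[positive] ** params.gamma * dist_term[positive]
    p[~off.astype(bool)] = 0.0
    np.fill_diagonal(p, 0.0)
    if not np.isfinite(p).all():
        raise ValueError("non-finite connection probabilities")
    return p


def rank_candidates(
    g: BrainGraph,
    p: np.ndarray,
    d: DistanceMatrix | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Sorted candidate lists for addition and deletion.

    Addition: absent pairs by P descending; deletion: present pairs by P
    ascending.  Ties in P break lexicographically on the (min-id, max-id)
    pair, except among P = 0 pairs, where distance decides first (shorter
    preferred for addition, longer for deletion) when a distance matrix is
    supplied.
    """
    order = np.asarray(g.node_ids)
    n = len(order)
    if p.shape != (n, n):
        raise ValueError("probability matrix shape does not match graph")
    iu, ju = np.triu_indices(n, k=1)
    pv = p[iu, ju]
    present = g.to_adjacency()[iu, ju].astype(bool)
    dv = d.values[iu, ju] if d is not None else np.zeros(len(iu))
    lo = np.minimum(order[iu], order[ju])
    hi = np.maximum(order[iu], order[ju])
    zero = pv == 0
    # among zero-probability pairs fall back to distance then lexicographic;
    # lexsort keys run from least to most significant
    def sort_pairs(mask: np.ndarray, descending: bool) -> list[tuple[int, int]]:
        idx = np.nonzero(mask)[0]
        score = -pv[idx] if descending else pv[idx]
        dist_key = np.where(zero[idx], dv[idx] if descending else -dv[idx], 0.0)
        ranked = idx[np.lexsort((hi[idx], lo[idx], dist_key, score))]
        return list(zip(lo[ranked].tolist(), hi[ranked].tolist()))

    additions = sort_pairs(~present, descending=True)
    deletions = sort_pairs(present, descending=False)
    return additions, deletions


def write_probability_matrix(
    p: np.ndarray, node_ids: tuple[int, ...], path: str | Path
) -> None:
    pd.DataFrame(p, index=node_ids, columns=node_ids).to_csv(path, sep="\t")
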