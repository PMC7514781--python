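"""Topological similarity scores for candidate connections.

Implements the classical neighborhood indices (common neighbors CN,
preferential attachment PA, Jaccard JC, Adamic-Adar AA, resource allocation
RA) and a mutual-information score MI that weights each common neighbor by
how informative its neighborhood is about link formation.

The MI score for a pair (u, v) with common-neighbor set ω is

    S_MI(u, v) = Σ_{z ∈ ω} I(L¹; z)  +  log p(L¹_{u,v})

where p(L¹_{m,n}) = 1 − C(|E|−k_m, k_n) / C(|E|, k_n) is the prior
probability that nodes of degrees k_m, k_n are linked when k_n edge stubs
are placed among |E| slots, and I(L¹; z) is the average, over ordered
neighbor pairs (m, n) of z, of the information gained about the link from
knowing z is a shared neighbor:

    I(L¹; z) = mean_{m≠n ∈ Γ(z)} [ −log p(L¹_{m,n}) + log p(L¹_{m,n} | z) ].

The conditional probability p(L¹ | z) is the clustering coefficient of z,
Laplace-smoothed so that triangle-free neighborhoods do not produce an
infinite self-information (see :func:`link_probability_given_neighbor`).
All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graph_core import BrainGraph

INDEX_NAMES = ("CN", "PA", "JC", "AA", "RA", "MI")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise scores S(u, v) for one index; symmetric, zero diagonal."""

    node_ids: tuple[int, ...]
    scores: np.ndarray
    index_name: str

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, index=self.node_ids, columns=self.node_ids).to_csv(
            path, sep="\t"
        )


def _check_pair(g: BrainGraph, u: int, v: int) -> None:
    if u == v:
        raise ValueError(f"similarity undefined for a node with itself ({u})")
    g.neighbors(u)  # raises UnknownNodeError if absent
    g.neighbors(v)


# ---------------------------------------------------------------------------
# Classical indices (per-pair)


def sim_cn(g: BrainGraph, u: int, v: int) -> int:
    """Common-neighbor count |Γ(u) ∩ Γ(v)|."""
    _check_pair(g, u, v)
    return len(g.neighbors(u) & g.neighbors(v))


def sim_pa(g: BrainGraph, u: int, v: int) -> float:
    """Preferential attachment |Γ(u)| × |Γ(v)|."""
    _check_pair(g, u, v)
    return float(g.degree(u) * g.degree(v))


def sim_jc(g: BrainGraph, u: int, v: int) -> float:
    """Jaccard |Γu ∩ Γv| / |Γu ∪ Γv|; 0 when both neighborhoods are empty."""
    _check_pair(g, u, v)
    gu, gv = g.neighbors(u), g.neighbors(v)
    union = len(gu | gv)
    return len(gu & gv) / union if union else 0.0


def sim_aa(g: BrainGraph, u: int, v: int) -> float:
    """Adamic-Adar Σ_{ξ ∈ Γu∩Γv} 1 / ln|Γ(ξ)| (common neighbors have degree ≥ 2)."""
    _check_pair(g, u, v)
    return sum(1.0 / log(g.degree(z)) for z in g.neighbors(u) & g.neighbors(v))


def sim_ra(g: BrainGraph, u: int, v: int) -> float:
    """Resource allocation Σ_{ξ ∈ Γu∩Γv} 1 / |Γ(ξ)|."""
    _check_pair(g, u, v)
    return sum(1.0 / g.degree(z) for z in g.neighbors(u) & g.neighbors(v))


# ---------------------------------------------------------------------------
# Mutual-information score components


def link_probability(e_count: int, km: int, kn: int) -> float:
    """Prior link probability p(L¹) = 1 − C(|E|−km, kn) / C(|E|, kn).

    Computed in log space via log-gamma so that connectome-scale edge counts
    (|E| ≈ 600) do not overflow.  C(a, b) = 0 whenever a < b, which makes the
    complement impossible and p = 1.
    """
    if km < 0 or kn < 0:
        raise ValueError("degrees must be nonnegative")
    if kn > e_count:
        raise ValueError(f"kn={kn} exceeds edge count {e_count}")
    if km == 0 or kn == 0:
        return 0.0
    if e_count - km < kn:
        return 1.0
    # log [C(E-km, kn) / C(E, kn)] = log (E-km)! + log (E-kn)! - log E! - log (E-km-kn)!
    log_ratio = (
        gammaln(e_count - km + 1)
        + gammaln(e_count - kn + 1)
        - gammaln(e_count + 1)
        - gammaln(e_count - km - kn + 1)
    )
    return float(min(1.0, max(0.0, -np.expm1(log_ratio))))


def link_probability_given_neighbor(g: BrainGraph, z: int, smoothed: bool = True) -> float:
    """Conditional link probability p(L¹ | z) = 2|Ez| / (|Γz|(|Γz|−1)).

    This is the clustering coefficient of z.  With ``smoothed=True`` (the
    default used by the MI score) a Laplace-style correction
    (2|Ez| + 1) / (|Γz|(|Γz|−1) + 2) keeps the value strictly inside (0, 1)
    so its logarithm stays finite for triangle-free neighborhoods.
    """
    dz = g.degree(z)
    if dz < 2:
        raise ValueError(f"node {z} has degree {dz} < 2; cannot be a common neighbor")
    ez = g.neighborhood_edge_count(z)
    if smoothed:
        return (2.0 * ez + 1.0) / (dz * (dz - 1.0) + 2.0)
    return 2.0 * ez / (dz * (dz - 1.0))


def neighbor_mutual_information(g: BrainGraph, z: int) -> float:
    """Average information I(L¹; z) a shared neighbor z carries about a link.

    Mean over ordered pairs m ≠ n in Γ(z) of
    −log p(L¹_{m,n}) + log p(L¹_{m,n} | z), with the smoothed conditional.
    """
    dz = g.degree(z)
    if dz < 2:
        raise ValueError(f"node {z} has degree {dz} < 2; cannot be a common neighbor")
    e = g.edge_count()
    log_cond = log(link_probability_given_neighbor(g, z, smoothed=True))
    nbrs = sorted(g.neighbors(z))
    total = 0.0
    for m in nbrs:
        for n in nbrs:
            if m == n:
                continue
            total += -log(link_probability(e, g.degree(m), g.degree(n))) + log_cond
    return total / (dz * (dz - 1.0))


def sim_mi(g: BrainGraph, u: int, v: int) -> float:
    """Mutual-information similarity S_MI(u, v) = Σ_z I(L¹; z) + log p(L¹_{u,v}).

    Returns −inf when either endpoint is isolated (the prior link
    probability is then zero); scores are ≤ 0 when no common neighbor
    contributes information and may take either sign otherwise.
    """
    _check_pair(g, u, v)
    p_prior = link_probability(g.edge_count(), g.degree(u), g.degree(v))
    prior_term = log(p_prior) if p_prior > 0.0 else -np.inf
    mi = sum(neighbor_mutual_information(g, z) for z in g.neighbors(u) & g.neighbors(v))
    return mi + prior_term


# ---------------------------------------------------------------------------
# Vectorized whole-matrix computation (used by the evolution engine, which
# re-scores every pair after every edge event)


def _log_link_prob_table(e_count: int, max_degree: int) -> np.ndarray:
    """Table T[a, b] = log p(L¹) for degree pair (a, b), 0 ≤ a, b ≤ max_degree.

    Entries with a = 0 or b = 0 are −inf (p = 0).
    """
    k = np.arange(max_degree + 1)
    a = k[:, None].astype(float)
    b = k[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = (
            gammaln(e_count - a + 1)
            + gammaln(e_count - b + 1)
            - gammaln(e_count + 1)
            - gammaln(np.maximum(e_count - a - b, 0) + 1)
        )
        p = -np.expm1(log_ratio)
        p[(a + b) > e_count] = 1.0
        p[(a == 0) | (b == 0)] = 0.0
        np.clip(p, 0.0, 1.0, out=p)
        return np.log(p)


def _mi_scores(a: np.ndarray) -> np.ndarray:
    """Dense S_MI matrix from a 0/1 adjacency (float64, zero diagonal)."""
    a = a.astype(float)
    n = a.shape[0]
    deg = a.sum(axis=1).astype(int)
    e_count = int(deg.sum()) // 2
    if e_count == 0:
        return np.full((n, n), -np.inf)
    logp = _log_link_prob_table(e_count, int(deg.max()))
    # per-node information weight w[z] = I(L¹; z); zero for degree < 2 nodes,
    # which can never be common neighbors
    fd = -logp[np.ix_(deg, deg)]  # self-information -log p per node pair
    fd[~np.isfinite(fd)] = 0.0  # degree-0 rows never appear as neighbors
    pair_sum = ((a @ fd) * a).sum(axis=1) - a @ np.diag(fd)
    ez = ((a @ a) * a).sum(axis=1) / 2.0
    dz = deg.astype(float)
    denom = dz * (dz - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = (2.0 * ez + 1.0) / (denom + 2.0)
        w = np.where(denom > 0, pair_sum / np.where(denom > 0, denom, 1.0) + np.log(p_cond), 0.0)
    scores = (a * w) @ a.T + logp[np.ix_(deg, deg)]
    np.fill_diagonal(scores, 0.0)
    return scores


def similarity_matrix(g: BrainGraph, index_name: str) -> SimilarityMatrix:
    """All-pairs scores for one index, computed with dense linear algebra."""
    index_name = index_name.upper()
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown similarity index {index_name!r}; choose from {INDEX_NAMES}")
    a = g.to_adjacency().astype(float)
    deg = a.sum(axis=1)
    cn = a @ a
    if index_name == "CN":
        scores = cn
    elif index_name == "PA":
        scores = np.outer(deg, deg)
    elif index_name == "JC":
        union = deg[:, None] + deg[None, :] - cn
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(union > 0, cn / np.where(union > 0, union, 1.0), 0.0)
    elif index_name == "AA":
        with np.errstate(divide="ignore"):
            inv = np.where(deg >= 2, 1.0 / np.log(np.maximum(deg, 2)), 0.0)
        scores = (a * inv) @ a.T
    elif index_name == "RA":
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        scores = (a * inv) @ a.T
    else:  # MI
        scores = _mi_scores(a)
    scores = np.asarray(scores, dtype=float)
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(g.node_ids, scores, index_name)
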