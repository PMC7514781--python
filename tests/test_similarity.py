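"""Similarity indices checked against independent brute-force oracles.

The oracles below re-derive every quantity from first principles with
``math.comb``/set loops, deliberately sharing no code with the package's
log-gamma / linear-algebra implementations.
"""

from itertools import combinations
from math import comb, log

import numpy as np
import pytest

from braingen import (
    link_probability,
    link_probability_given_neighbor,
    neighbor_mutual_information,
    sim_aa,
    sim_cn,
    sim_jc,
    sim_mi,
    sim_pa,
    sim_ra,
    similarity_matrix,
)
from braingen.graph_core import BrainGraph

from conftest import random_graph


# -- independent oracles -----------------------------------------------------


def oracle_link_prob(e_count, km, kn):
    if e_count - km < kn:
        return 1.0
    return 1.0 - comb(e_count - km, kn) / comb(e_count, kn)


def oracle_cond_prob(g, z):
    nbrs = sorted(g.neighbors(z))
    ez = sum(1 for m, n in combinations(nbrs, 2) if g.has_edge(m, n))
    return (2 * ez + 1) / (len(nbrs) * (len(nbrs) - 1) + 2)


def oracle_nmi(g, z):
    e = g.edge_count()
    nbrs = sorted(g.neighbors(z))
    total = 0.0
    for m in nbrs:
        for n in nbrs:
            if m != n:
                total += -log(oracle_link_prob(e, g.degree(m), g.degree(n))) + log(
                    oracle_cond_prob(g, z)
                )
    return total / (len(nbrs) * (len(nbrs) - 1))


def oracle_sim_mi(g, u, v):
    e = g.edge_count()
    prior = oracle_link_prob(e, g.degree(u), g.degree(v))
    base = log(prior) if prior > 0 else -np.inf
    return base + sum(oracle_nmi(g, z) for z in g.neighbors(u) & g.neighbors(v))


ORACLES = {
    "CN": lambda g, u, v: len(g.neighbors(u) & g.neighbors(v)),
    "PA": lambda g, u, v: g.degree(u) * g.degree(v),
    "JC": lambda g, u, v: (
        len(g.neighbors(u) & g.neighbors(v)) / len(g.neighbors(u) | g.neighbors(v))
        if g.neighbors(u) | g.neighbors(v)
        else 0.0
    ),
    "AA": lambda g, u, v: sum(1 / log(g.degree(z)) for z in g.neighbors(u) & g.neighbors(v)),
    "RA": lambda g, u, v: sum(1 / g.degree(z) for z in g.neighbors(u) & g.neighbors(v)),
    "MI": oracle_sim_mi,
}

SCALAR_OPS = {"CN": sim_cn, "PA": sim_pa, "JC": sim_jc, "AA": sim_aa, "RA": sim_ra, "MI": sim_mi}


# -- classical indices -------------------------------------------------------


class TestClassicalIndices:
    def test_cn_disjoint_and_shared(self, path3):
        assert sim_cn(path3, 1, 3) == 1  # path 1-2-3: node 2 shared
        g = BrainGraph([1, 2, 3, 4], [(1, 2), (3, 4)])
        assert sim_cn(g, 1, 3) == 0

    def test_pa_degree_product(self, star5):
        assert sim_pa(star5, 2, 3) == 1.0
        assert sim_pa(star5, 1, 2) == 5.0

    def test_jc_worked_example(self):
        g = BrainGraph(
            range(1, 7),
            [(1, 3), (1, 4), (1, 5), (2, 4), (2, 5), (2, 6)],
        )
        # neighborhoods {3,4,5} and {4,5,6}: 2 shared of 4 total
        assert sim_jc(g, 1, 2) == pytest.approx(0.5)

    def test_jc_degenerate_isolated_pair(self):
        g = BrainGraph([1, 2, 3])
        assert sim_jc(g, 1, 2) == 0.0

    def test_aa_single_common_neighbor_degree_two(self, path3):
        assert sim_aa(path3, 1, 3) == pytest.approx(1 / log(2))

    def test_ra_two_common_neighbors(self):
        g = BrainGraph(
            range(1, 9),
            [(1, 3), (2, 3), (1, 4), (2, 4), (4, 5), (4, 6)],
        )
        # common neighbors of (1,2): node 3 (degree 2) and node 4 (degree 4)
        assert sim_ra(g, 1, 2) == pytest.approx(0.5 + 0.25)

    def test_same_node_rejected(self, triangle):
        for op in SCALAR_OPS.values():
            with pytest.raises(ValueError):
                op(triangle, 1, 1)

    @pytest.mark.parametrize("index", list(ORACLES))
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, index, seed):
        g = random_graph(18, 0.25, seed)
        op = SCALAR_OPS[index]
        oracle = ORACLES[index]
        for u, v in [(1, 2), (3, 10), (5, 18), (7, 11)]:
            assert op(g, u, v) == pytest.approx(oracle(g, u, v))

    @pytest.mark.parametrize("index", list(ORACLES))
    def test_symmetry(self, index):
        g = random_graph(16, 0.3, 11)
        op = SCALAR_OPS[index]
        for u, v in [(1, 5), (2, 9), (4, 16)]:
            assert op(g, u, v) == pytest.approx(op(g, v, u))

    @pytest.mark.parametrize("index", list(ORACLES))
    @pytest.mark.parametrize("seed", range(3))
    def test_matrix_matches_scalar_ops(self, index, seed):
        g = random_graph(14, 0.3, seed + 40)
        s = similarity_matrix(g, index)
        op = SCALAR_OPS[index]
        order = g.node_ids
        for i, u in enumerate(order):
            for j, v in enumerate(order):
                if i < j:
                    assert s.scores[i, j] == pytest.approx(op(g, u, v), abs=1e-10)


# -- link probability --------------------------------------------------------


class TestLinkProbability:
    def test_zero_degree_gives_zero(self):
        assert link_probability(10, 0, 4) == 0.0
        assert link_probability(10, 4, 0) == 0.0

    def test_impossible_complement_gives_one(self):
        assert link_probability(3, 2, 2) == 1.0

    def test_small_case_exact_fraction(self):
        assert link_probability(10, 3, 2) == pytest.approx(1 - 21 / 45)

    def test_kn_above_edge_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            link_probability(5, 2, 6)

    @pytest.mark.parametrize("e_count", [4, 7, 12])
    def test_matches_exhaustive_enumeration(self, e_count):
        """p equals the fraction of kn-subsets of E slots hitting a km block."""
        for km in range(0, e_count + 1):
            for kn in range(0, e_count + 1):
                slots = range(e_count)
                marked = set(range(km))
                subsets = list(combinations(slots, kn))
                hit = sum(1 for s in subsets if marked & set(s))
                assert link_probability(e_count, km, kn) == pytest.approx(
                    hit / len(subsets)
                )

    def test_monotone_in_degrees_and_symmetric(self):
        e = 50
        vals = [[link_probability(e, a, b) for b in range(12)] for a in range(12)]
        arr = np.array(vals)
        assert np.all(np.diff(arr, axis=0) >= -1e-12)
        assert np.all(np.diff(arr, axis=1) >= -1e-12)
        assert np.allclose(arr, arr.T)
        assert np.all((arr >= 0) & (arr <= 1))


# -- conditional probability and mutual information --------------------------


class TestConditionalProbability:
    def test_k4_smoothing(self, k4):
        assert link_probability_given_neighbor(k4, 1, smoothed=False) == pytest.approx(1.0)
        assert link_probability_given_neighbor(k4, 1) == pytest.approx(7 / 8)

    def test_star_center_smoothing(self):
        g = BrainGraph([1, 2, 3, 4], [(1, 2), (1, 3), (1, 4)])
        assert link_probability_given_neighbor(g, 1, smoothed=False) == 0.0
        assert link_probability_given_neighbor(g, 1) == pytest.approx(1 / 8)

    def test_partial_clustering_raw_value(self):
        g = BrainGraph(range(1, 6), [(1, 2), (1, 3), (1, 4), (1, 5), (2, 3), (4, 5)])
        assert link_probability_given_neighbor(g, 1, smoothed=False) == pytest.approx(1 / 3)

    def test_low_degree_rejected(self, triangle_pendant):
        with pytest.raises(ValueError, match="degree"):
            link_probability_given_neighbor(triangle_pendant, 4)


class TestMutualInformation:
    def test_constant_degree_neighbors_average_is_single_term(self, k4):
        # all neighbor pairs of node 1 in K4 have equal degrees
        e, d = k4.edge_count(), 3
        single = -log(link_probability(e, d, d)) + log(7 / 8)
        assert neighbor_mutual_information(k4, 1) == pytest.approx(single)

    def test_fixture_matches_oracle(self, mi_fixture):
        for z in mi_fixture.node_ids:
            if mi_fixture.degree(z) >= 2:
                assert neighbor_mutual_information(mi_fixture, z) == pytest.approx(
                    oracle_nmi(mi_fixture, z)
                )

    def test_finite_for_all_valid_neighbors(self):
        g = random_graph(20, 0.2, 5)
        for z in g.node_ids:
            if g.degree(z) >= 2:
                assert np.isfinite(neighbor_mutual_information(g, z))

    def test_empty_common_neighborhood_reduces_to_prior(self):
        g = BrainGraph([1, 2, 3, 4], [(1, 2), (3, 4)])
        expected = log(link_probability(2, 1, 1))
        assert sim_mi(g, 1, 3) == pytest.approx(expected)
        assert sim_mi(g, 1, 3) <= 0.0

    def test_fixture_matches_end_to_end_oracle(self, mi_fixture):
        for u in mi_fixture.node_ids:
            for v in mi_fixture.node_ids:
                if u < v:
                    assert sim_mi(mi_fixture, u, v) == pytest.approx(
                        oracle_sim_mi(mi_fixture, u, v)
                    )
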