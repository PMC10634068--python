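"""Attribute diversity and the model-based scores AB, PWS, PHY.

Oracles: direct closed-form evaluations and a naive pure-Python
average-linkage clustering, independent of the scipy-backed implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meh.distances import DistanceMatrix, distance_matrix
from meh.hill import (
    AttributeSystem,
    ab_score,
    attribute_diversity,
    build_pattern_tree,
    phy_score,
    pws_score,
)
from meh.patterns import as_pattern_counts

from conftest import random_counts


def naive_upgma_branches(d, p):
    """Reference average-linkage clustering returning (length, abundance) branches.

    Only valid when every merge decision is tie-free.
    """
    n = len(p)
    members = {i: [i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    dist = {frozenset((i, j)): d[i][j] for i in range(n) for j in range(i + 1, n)}
    branches = []
    active = set(members)
    nxt = n
    while len(active) > 1:
        pairs = sorted(dist.items(), key=lambda kv: kv[1])
        assert len(pairs) < 2 or pairs[1][1] - pairs[0][1] > 1e-12, "tie-free case required"
        (pair, dmin) = pairs[0]
        a, b = sorted(pair)
        h = dmin / 2
        for c in (a, b):
            branches.append((h - heights[c], sum(p[m] for m in members[c])))
        members[nxt] = members[a] + members[b]
        heights[nxt] = h
        na, nb = len(members[a]), len(members[b])
        for other in active - {a, b}:
            dist[frozenset((nxt, other))] = (
                dist[frozenset((a, other))] * na + dist[frozenset((b, other))] * nb
            ) / (na + nb)
        active -= {a, b}
        active.add(nxt)
        dist = {k: v for k, v in dist.items() if all(x in active for x in k)}
        nxt += 1
    return branches


def naive_phy(branches):
    """Direct loop evaluation of PHY from (length, abundance) branches."""
    total = sum(length * p for length, p in branches)
    return 1.0 / sum(length * (p / total) ** 2 for length, p in branches)


class TestAttributeDiversity:
    def test_unit_attributes_q2_is_reciprocal_simpson(self):
        sys = AttributeSystem(values=[1, 1], abundances=[0.5, 0.5], q=2)
        assert attribute_diversity(sys) == pytest.approx(2.0)

    def test_single_entity_diversity_equals_its_attribute_value(self):
        # a single entity contributes exactly its attribute value; with a
        # unit attribute the diversity of one entity is 1
        sys = AttributeSystem(values=[3.7], abundances=[5.0], q=2)
        assert attribute_diversity(sys) == pytest.approx(3.7)
        unit = AttributeSystem(values=[1.0], abundances=[5.0], q=2)
        assert attribute_diversity(unit) == pytest.approx(1.0)

    def test_q1_limit_is_exp_shannon(self):
        sys = AttributeSystem(values=[1] * 4, abundances=[0.25] * 4, q=1)
        assert attribute_diversity(sys) == pytest.approx(4.0)

    def test_q0_counts_entities_with_unit_attributes(self):
        sys = AttributeSystem(values=[1, 1, 1], abundances=[0.9, 0.05, 0.05], q=0)
        assert attribute_diversity(sys) == pytest.approx(3.0)

    def test_all_zero_abundances_rejected(self):
        with pytest.raises(ValueError):
            attribute_diversity(AttributeSystem(values=[1.0], abundances=[0.0], q=2))

    def test_ab_is_q2_specialization_with_unit_attributes(self, rng):
        for _ in range(50):
            pc = random_counts(rng)
            sys = AttributeSystem(
                values=np.ones(pc.n_patterns), abundances=pc.abundances(), q=2
            )
            assert ab_score(pc) == pytest.approx(attribute_diversity(sys), abs=1e-12)


class TestAbScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"0000": 4}, 1.0),
            ({"0000": 2, "1111": 2}, 2.0),
            ({"0000": 3, "1111": 1}, 1.6),
        ],
    )
    def test_frozen_examples(self, counts, expected):
        assert ab_score(counts) == pytest.approx(expected)

    def test_equals_pattern_count_at_uniform(self):
        counts = {format(i, "04b"): 3 for i in range(16)}
        assert ab_score(counts) == pytest.approx(16.0)

    def test_range_bounds(self, rng):
        for _ in range(100):
            pc = random_counts(rng)
            assert 1.0 - 1e-12 <= ab_score(pc) <= 2 ** pc.window.w + 1e-12

    def test_depends_only_on_abundance_vector(self):
        # relabeling patterns leaves AB unchanged
        assert ab_score({"0000": 3, "0001": 1}) == ab_score({"1010": 3, "0101": 1})


class TestPwsScore:
    def test_two_maximally_distant_patterns_score_sqrt2(self):
        assert pws_score({"0000": 2, "1111": 2}) == pytest.approx(math.sqrt(2))

    def test_two_pattern_closed_form_sqrt_2d(self):
        # PWS of two equally abundant patterns at distance d is sqrt(2d)
        assert pws_score({"0000": 2, "0001": 2}) == pytest.approx(math.sqrt(0.5))
        assert pws_score({"0000": 5, "0011": 5}) == pytest.approx(1.0)

    def test_homogeneous_window_is_zero(self):
        assert pws_score({"0000": 4}) == 0.0

    def test_strictly_increasing_in_distance_at_fixed_abundances(self):
        pc = as_pattern_counts({"0011": 2, "0111": 2})
        low = pws_score(pc)
        dm = DistanceMatrix(("0011", "0111"), np.array([[0.0, 0.9], [0.9, 0.0]]))
        assert pws_score(pc, dist=dm) > low

    def test_metric_choice_changes_score(self):
        pc = {"0000": 2, "0001": 2}
        assert pws_score(pc, metric="wdk") != pytest.approx(pws_score(pc, metric="hamming"))


class TestPatternTree:
    def test_five_patterns_give_eight_branches(self):
        pc = as_pattern_counts({"0000": 1, "0001": 1, "0011": 1, "0111": 1, "1111": 1})
        tree = build_pattern_tree(distance_matrix(pc.patterns), pc)
        assert tree.n_branches == 8

    def test_branch_count_is_2r_minus_2(self, rng):
        for _ in range(20):
            pc = random_counts(rng, min_depth=4)
            if pc.n_patterns < 2:
                continue
            tree = build_pattern_tree(distance_matrix(pc.patterns), pc)
            assert tree.n_branches == 2 * pc.n_patterns - 2

    def test_two_patterns_at_distance_one_split_half_lengths(self):
        pc = as_pattern_counts({"0000": 2, "1111": 2})
        tree = build_pattern_tree(distance_matrix(pc.patterns), pc)
        assert tree.lengths.tolist() == [0.5, 0.5]
        assert tree.abundances.tolist() == [0.5, 0.5]

    def test_internal_branch_abundance_sums_descendant_leaves(self):
        pc = as_pattern_counts({"0000": 2, "0001": 1, "1111": 1})
        tree = build_pattern_tree(distance_matrix(pc.patterns), pc)
        # closest pair (0000, 0001) merges first; its branch carries p1 + p2
        assert 0.75 in np.round(tree.abundances, 12)
        # every branch abundance is a partial sum of leaf abundances in (0, 1]
        assert np.all(tree.abundances > 0) and np.all(tree.abundances <= 1 + 1e-12)

    def test_single_pattern_rejected(self):
        pc = as_pattern_counts({"0000": 4})
        with pytest.raises(ValueError):
            build_pattern_tree(distance_matrix(pc.patterns), pc)

    @pytest.mark.parametrize(
        "counts",
        [
            {"0101": 4, "1001": 5, "1110": 1},
            {"0001": 2, "1100": 1, "1111": 3},
            {"0110": 4, "0111": 1, "1010": 3, "1101": 2},
            {"0000": 4, "0011": 5, "0100": 3, "0110": 4, "0111": 5},
            {"0011": 5, "0110": 2, "1000": 4, "1001": 5, "1100": 4},
        ],
    )
    def test_matches_naive_average_linkage_on_tie_free_cases(self, counts):
        # weighted-degree-kernel distances make all merge decisions unique here
        pc = as_pattern_counts(counts)
        dm = distance_matrix(pc.patterns, metric="wdk")
        tree = build_pattern_tree(dm, pc)
        naive = naive_upgma_branches(dm.d.tolist(), pc.abundances().tolist())
        impl = sorted(zip(np.round(tree.lengths, 10), np.round(tree.abundances, 10)))
        ref = sorted((round(l, 10), round(a, 10)) for l, a in naive)
        assert impl == ref


class TestPhyScore:
    def test_two_equal_patterns_distance_one_scores_one(self):
        assert phy_score({"0000": 2, "1111": 2}) == pytest.approx(1.0)

    def test_homogeneous_window_is_zero(self):
        assert phy_score({"0000": 7}) == 0.0

    def test_matches_direct_formula_evaluation(self, rng):
        for _ in range(50):
            pc = random_counts(rng, min_depth=4)
            if pc.n_patterns < 2:
                continue
            tree = build_pattern_tree(distance_matrix(pc.patterns), pc)
            branches = list(zip(tree.lengths.tolist(), tree.abundances.tolist()))
            assert phy_score(pc, tree=tree) == pytest.approx(naive_phy(branches), abs=1e-12)

    def test_zero_length_tree_rejected(self):
        pc = as_pattern_counts({"00": 1, "01": 1})
        dm = DistanceMatrix(("00", "01"), np.zeros((2, 2)))
        tree = build_pattern_tree(dm, pc)
        with pytest.raises(ValueError, match="branch lengths"):
            phy_score(pc, tree=tree)


class TestModelScoreInvariants:
    """The framework's axioms: scale invariance, monotonicity, doubling."""

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_scale_invariance(self, rng, k):
        for _ in range(20):
            pc = random_counts(rng, min_depth=2)
            scaled = pc.scaled(k)
            assert ab_score(scaled) == pytest.approx(ab_score(pc), abs=1e-9)
            assert pws_score(scaled) == pytest.approx(pws_score(pc), abs=1e-9)
            assert phy_score(scaled) == pytest.approx(phy_score(pc), abs=1e-9)

    @pytest.mark.parametrize(
        "base,new",
        [
            ({"0000": 4}, "1111"),
            ({"0000": 4, "0011": 2}, "1111"),
            ({"1111": 6, "1100": 2}, "0000"),
        ],
    )
    def test_weak_monotonicity_adding_maximally_distant_pattern(self, base, new):
        grown = dict(base)
        grown[new] = 1
        for score in (ab_score, pws_score, phy_score):
            assert score(grown) > score(base)

    def test_ab_doubling_on_disjoint_equal_pools(self):
        # two windows, disjoint pattern sets, equal AB, equal depth -> pooled AB doubles
        w1 = {"0000": 2, "0001": 2}
        w2 = {"1110": 2, "1111": 2}
        pooled = {**w1, **w2}
        assert ab_score(w1) == pytest.approx(ab_score(w2))
        assert ab_score(pooled) == pytest.approx(2 * ab_score(w1), abs=1e-9)

    def test_pws_doubling_on_constructed_pair_pools(self):
        # pair-level diversity quadruples -> PWS doubles: two disjoint
        # equal-abundance pairs with within-distance d and cross-distance d/2
        d, dc = 0.5, 0.25
        pats = ("0000", "0011", "1100", "1111")
        dmat = np.array(
            [[0, d, dc, dc], [d, 0, dc, dc], [dc, dc, 0, d], [dc, dc, d, 0]], dtype=float
        )
        single = pws_score({"0000": 2, "0011": 2})  # hamming d = 0.5
        pooled = pws_score(
            {p: 1 for p in pats}, dist=DistanceMatrix(pats, dmat)
        )
        assert single == pytest.approx(1.0)
        assert pooled == pytest.approx(2 * single, abs=1e-9)


@given(
    st.dictionaries(
        st.text(alphabet="01", min_size=4, max_size=4),
        st.integers(min_value=1, max_value=30),
        min_size=1,
        max_size=8,
    )
)
@settings(max_examples=150, deadline=None)
def test_scores_are_finite_and_nonnegative(counts):
    assert ab_score(counts) >= 1.0 - 1e-12
    assert pws_score(counts) >= 0.0
    assert phy_score(counts) >= 0.0
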