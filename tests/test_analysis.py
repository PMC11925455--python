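"""Strength of influence and parameter sensitivity."""

import itertools

import numpy as np
import pytest

from conftest import make_bn, random_bn
from rtsbn.analysis import (
    influential_node_set,
    joint_marginal,
    sensitivity_to_parameters,
    strength_of_influence,
    tornado_data,
)
from rtsbn.errors import ConfigurationError
from rtsbn.inference import posterior


def brute_force_strength(bn, arc, distance_kind="euclidean"):
    """Straight-line reimplementation: loop over every pair and configuration."""
    parent, child = arc
    cpt = bn.cpts[child]
    ax = cpt.parents.index(parent)
    cards = cpt.parent_cards
    k = cards[ax]
    totals, count = 0.0, 0
    other_axes = [i for i in range(len(cards)) if i != ax]
    other_ranges = [range(cards[i]) for i in other_axes]
    for combo in itertools.product(*other_ranges) if other_axes else [()]:
        for i, j in itertools.combinations(range(k), 2):
            idx_i, idx_j = list(combo), list(combo)
            idx_i.insert(ax, i)
            idx_j.insert(ax, j)
            a = cpt.table[cpt.row_index(idx_i)]
            b = cpt.table[cpt.row_index(idx_j)]
            if distance_kind == "euclidean":
                d = np.linalg.norm(a - b) / np.sqrt(2)
            elif distance_kind == "tv":
                d = 0.5 * np.abs(a - b).sum()
            else:
                d = np.sqrt(0.5 * ((np.sqrt(a) - np.sqrt(b)) ** 2).sum())
            totals += d
            count += 1
    return totals / count * (1 if other_axes else 1)


class TestStrengthOfInfluence:
    def test_identical_rows_score_zero(self):
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0")},
            {("A", "B")},
            {"A": [[0.5, 0.5]], "B": [[0.7, 0.3], [0.7, 0.3]]},
        )
        assert strength_of_influence(bn, ("A", "B")) == 0.0

    def test_deterministic_swap_scores_one(self):
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0")},
            {("A", "B")},
            {"A": [[0.5, 0.5]], "B": [[1.0, 0.0], [0.0, 1.0]]},
        )
        assert strength_of_influence(bn, ("A", "B")) == pytest.approx(1.0)

    @pytest.mark.parametrize("distance", ["euclidean", "hellinger", "tv"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_networks(self, seed, distance):
        bn = random_bn(np.random.default_rng(50 + seed), max_nodes=6, max_states=4)
        arcs = sorted(bn.structure.arcs)
        if not arcs:
            pytest.skip("arc-free draw")
        for arc in arcs:
            got = strength_of_influence(bn, arc, distance_kind=distance)
            want = brute_force_strength(bn, arc, distance)
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_joint_weighting_matches_hand_average(self):
        # child with two parents; weight configs of the other parent by its
        # marginal probability
        bn = make_bn(
            {"A": ("a1", "a0"), "C": ("c1", "c0"), "B": ("b1", "b0")},
            {("A", "B"), ("C", "B")},
            {
                "A": [[0.5, 0.5]],
                "C": [[0.8, 0.2]],
                "B": [
                    [1.0, 0.0],  # a1 c1
                    [0.6, 0.4],  # a1 c0
                    [0.0, 1.0],  # a0 c1
                    [0.6, 0.4],  # a0 c0
                ],
            },
        )
        d_c1 = 1.0  # swap between point masses
        d_c0 = 0.0
        want = 0.8 * d_c1 + 0.2 * d_c0
        got = strength_of_influence(bn, ("A", "B"), weighting="joint")
        assert got == pytest.approx(want, abs=1e-12)

    def test_absent_arc_rejected(self, chain_ab):
        with pytest.raises(ConfigurationError):
            strength_of_influence(chain_ab, ("B", "A"))


def test_joint_marginal_sums_to_one(canonical_bn):
    m = joint_marginal(canonical_bn, ("type_injury", "body_region"))
    assert m.shape == (7, 17)
    assert m.sum() == pytest.approx(1.0, abs=1e-9)


class TestSensitivity:
    def test_chain_derivative_equals_conditional_difference(self, chain_ab):
        # d P(B=b1) / d P(A=a1) = P(b1|a1) - P(b1|a0) under co-variation
        report = sensitivity_to_parameters(chain_ab, "B", "b1")
        derivs = {
            (node, row, k): d for node, row, k, d in report.derivatives
        }
        assert derivs[("A", 0, 0)] == pytest.approx(0.9 - 0.2, abs=1e-6)

    def test_d_separated_nodes_flagged_exactly_zero(self):
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0"), "C": ("c1", "c0")},
            {("A", "B"), ("B", "C")},
            {
                "A": [[0.3, 0.7]],
                "B": [[0.9, 0.1], [0.2, 0.8]],
                "C": [[0.8, 0.2], [0.1, 0.9]],
            },
        )
        report = sensitivity_to_parameters(bn, "C", "c1", {"B": "b1"})
        assert "A" in report.zero_flagged
        assert report.aggregates["A"] == 0.0
        # B's own CPT cancels from P(C | B=b1) in a chain: also flagged
        assert report.aggregates["B"] == 0.0

    def test_barren_leaf_is_non_influential(self, chain_ab):
        report = sensitivity_to_parameters(chain_ab, "A", "a1")
        assert report.aggregates["B"] == 0.0  # B unobserved descendant

    def test_deterministic_child_target_sees_parent(self):
        # days -> severity style chain: the deterministic child's posterior
        # responds to the parent's parameters
        bn = make_bn(
            {"D": ("d1", "d2", "d3"), "S": ("s1", "s2")},
            {("D", "S")},
            {
                "D": [[0.5, 0.3, 0.2]],
                "S": [[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]],
            },
        )
        report = sensitivity_to_parameters(bn, "S", "s2")
        assert report.aggregates["D"] > 0.1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_stable_under_step_halving(self, seed):
        bn = random_bn(np.random.default_rng(90 + seed), max_nodes=4, max_states=3)
        target = bn.nodes[-1]
        state = bn.states(target)[0]
        r1 = sensitivity_to_parameters(bn, target, state, step=1e-5)
        r2 = sensitivity_to_parameters(bn, target, state, step=5e-6)
        for node in bn.nodes:
            assert r1.aggregates[node] == pytest.approx(
                r2.aggregates[node], abs=1e-6
            )


class TestInfluentialNodes:
    def test_chain_partition(self):
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0"), "C": ("c1", "c0")},
            {("A", "B"), ("B", "C")},
            {
                "A": [[0.3, 0.7]],
                "B": [[0.9, 0.1], [0.2, 0.8]],
                "C": [[0.8, 0.2], [0.1, 0.9]],
            },
        )
        report = sensitivity_to_parameters(bn, "C", "c1")
        influential, grey = influential_node_set(report, threshold=0.0)
        assert influential == {"A", "B"}
        report_blocked = sensitivity_to_parameters(bn, "C", "c1", {"B": "b1"})
        influential, grey = influential_node_set(report_blocked, threshold=0.0)
        assert "A" in grey

    def test_negative_threshold_rejected(self, chain_ab):
        report = sensitivity_to_parameters(chain_ab, "B", "b1")
        with pytest.raises(ConfigurationError):
            influential_node_set(report, threshold=-1)


class TestTornado:
    def test_top_m_clamped_to_parameter_count(self, chain_ab):
        rows = tornado_data(chain_ab, "B", "b1", top_m=1000, spread=0.1)
        n_params = sum(c.table.size for c in chain_ab.cpts.values())
        assert len(rows) == n_params

    def test_intervals_contain_base_posterior(self, chain_ab):
        base = posterior(chain_ab, "B")["b1"]
        for _, lo, hi in tornado_data(chain_ab, "B", "b1", top_m=4, spread=0.05):
            assert lo - 1e-9 <= base <= hi + 1e-9

    def test_ranked_by_interval_width(self, chain_ab):
        rows = tornado_data(chain_ab, "B", "b1", top_m=6, spread=0.1)
        widths = [hi - lo for _, lo, hi in rows]
        assert widths == sorted(widths, reverse=True)

    def test_bad_spread_rejected(self, chain_ab):
        with pytest.raises(ConfigurationError):
            tornado_data(chain_ab, "B", "b1", spread=1.5)
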