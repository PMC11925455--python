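"""Parameter estimation (ML, EM) and constrained structure search."""

import itertools

import numpy as np
import pytest

from conftest import make_bn
from rtsbn.dataset import Dataset
from rtsbn.errors import ConfigurationError
from rtsbn.learning import (
    LearningConfig,
    bayesian_search,
    bdeu_score,
    fit_parameters_em,
    fit_parameters_ml,
)
from rtsbn.network import NetworkStructure
from rtsbn.schema import MISSING, Tier, VariableSpec
from rtsbn.simulate import inject_missing, sample_dataset


def _toy_schema():
    return (
        VariableSpec("A", Tier.PERSONAL, ("a1", "a0")),
        VariableSpec("B", Tier.PERSONAL, ("b1", "b0")),
    )


def _toy_dataset(rows):
    return Dataset(_toy_schema(), [{"A": a, "B": b} for a, b in rows])


def _ab_structure(arcs={("A", "B")}):
    return NetworkStructure(
        ("A", "B"), frozenset(arcs), {"A": Tier.PERSONAL, "B": Tier.PERSONAL}
    )


@pytest.fixture(scope="module")
def five_node_bn():
    """Tiered 5-node ground truth with strong dependencies."""
    def strong_rows(q, r):
        # rows concentrated on a rotating dominant state: decisive yet noisy
        rows = np.full((q, r), 0.1 / (r - 1))
        for j in range(q):
            rows[j, j % r] = 0.9
        return rows

    def days_rows():
        # dominant day class shifts with every parent (a+s+t mod 3), so each
        # parent carries strong signal marginally and conditionally
        rows = np.full((18, 3), 0.05)
        i = 0
        for a in range(3):
            for s in range(3):
                for t in range(2):
                    rows[i, (a + s + t) % 3] = 0.9
                    i += 1
        return rows

    variables = {
        "v_age": ("y", "m", "o"),
        "v_site": ("x1", "x2", "x3"),
        "v_type": ("t1", "t2"),
        "v_days": ("d1", "d2", "d3"),
        "v_sev": ("s1", "s2"),
    }
    # pure collider at v_days: every arc is compelled, so the DAG is the
    # unique member of its equivalence class; every parent configuration has
    # probability >= 0.02, so n=20,000 populates each row decisively
    arcs = {
        ("v_age", "v_days"),
        ("v_site", "v_days"),
        ("v_type", "v_days"),
        ("v_days", "v_sev"),
    }
    tiers = {
        "v_age": Tier.PERSONAL,
        "v_site": Tier.INJURY,
        "v_type": Tier.INJURY,
        "v_days": Tier.OUTCOME_DAYS,
        "v_sev": Tier.OUTCOME_SEVERITY,
    }
    tables = {
        "v_age": [[0.4, 0.35, 0.25]],
        "v_site": [[0.45, 0.35, 0.2]],
        "v_type": [[0.6, 0.4]],
        "v_days": days_rows(),
        "v_sev": strong_rows(3, 2),
    }
    return make_bn(variables, arcs, tables, tiers)


class TestMaximumLikelihood:
    def test_empirical_frequency(self):
        ds = _toy_dataset([("a1", "b1")] * 7 + [("a0", "b1")] * 3)
        cpts = fit_parameters_ml(_ab_structure(set()), ds, pseudocount=0.0)
        assert cpts["A"].table[0, 0] == pytest.approx(0.7)

    def test_unseen_configuration_uniform_under_smoothing(self):
        ds = _toy_dataset([("a1", "b1")] * 5)
        cpts = fit_parameters_ml(_ab_structure(), ds, pseudocount=1.0)
        row_a0 = cpts["B"].table[1]
        np.testing.assert_allclose(row_a0, [0.5, 0.5])

    def test_hand_tallied_smoothed_frequencies(self):
        rows = [("a1", "b1")] * 4 + [("a1", "b0")] * 2 + [("a0", "b1")] + [("a0", "b0")] * 3
        cpts = fit_parameters_ml(_ab_structure(), _toy_dataset(rows), pseudocount=1.0)
        np.testing.assert_allclose(cpts["B"].table[0], [5 / 8, 3 / 8])
        np.testing.assert_allclose(cpts["B"].table[1], [2 / 6, 4 / 6])
        np.testing.assert_allclose(cpts["A"].table[0], [7 / 12, 5 / 12])

    def test_missing_values_direct_to_em(self):
        ds = Dataset(_toy_schema(), [{"A": "a1", "B": MISSING}])
        with pytest.raises(ConfigurationError, match="fit_parameters_em"):
            fit_parameters_ml(_ab_structure(), ds)


class TestEM:
    def test_complete_data_reduces_to_ml(self, five_node_bn):
        ds = sample_dataset(five_node_bn, 500, seed=3)
        config = LearningConfig(pseudocount=1.0, seed=11)
        ml = fit_parameters_ml(five_node_bn.structure, ds, pseudocount=1.0)
        em, trace = fit_parameters_em(five_node_bn.structure, ds, config)
        for node in five_node_bn.nodes:
            np.testing.assert_allclose(em[node].table, ml[node].table, atol=1e-9)
        # first M-step already lands on the ML optimum
        assert len(trace) <= 3

    def test_trace_monotone_under_missingness(self, five_node_bn):
        ds = inject_missing(sample_dataset(five_node_bn, 800, seed=4), 0.3, seed=5)
        _, trace = fit_parameters_em(
            five_node_bn.structure, ds, LearningConfig(pseudocount=1.0, seed=2)
        )
        assert len(trace) >= 2
        for a, b in zip(trace, trace[1:]):
            assert b >= a - 1e-6 * max(1.0, abs(a))

    def test_fully_missing_variable_rejected(self):
        ds = Dataset(
            _toy_schema(), [{"A": "a1", "B": MISSING}, {"A": "a0", "B": MISSING}]
        )
        with pytest.raises(ConfigurationError, match="missing in every record"):
            fit_parameters_em(_ab_structure(), ds, LearningConfig())

    def test_parameter_recovery_under_mcar(self, five_node_bn):
        # n=20,000 draw, 20% missing completely at random
        ds = sample_dataset(five_node_bn, 20_000, seed=7)
        missing = inject_missing(ds, 0.2, seed=8)
        config = LearningConfig(pseudocount=0.5, seed=1, em_tol=1e-5)
        ml = fit_parameters_ml(five_node_bn.structure, ds, pseudocount=0.0)
        em, _ = fit_parameters_em(five_node_bn.structure, missing, config)
        for node in five_node_bn.nodes:
            true = five_node_bn.cpts[node].table
            assert np.abs(ml[node].table - true).max() < 0.05
            assert np.abs(em[node].table - true).max() < 0.08


class TestBdeuScore:
    def test_decomposability_single_family_change(self, five_node_bn):
        # adding one arc shifts the score by the same amount whatever the
        # rest of the graph looks like (only the child's family term moves)
        ds = sample_dataset(five_node_bn, 400, seed=9)
        tiers = {s.name: s.tier for s in ds.schema}
        nodes = tuple(ds.variable_names)
        empty = NetworkStructure(nodes, frozenset(), tiers)
        other = NetworkStructure(nodes, frozenset({("v_site", "v_type")}), tiers)
        delta_from_empty = bdeu_score(
            NetworkStructure(nodes, frozenset({("v_age", "v_days")}), tiers), ds
        ) - bdeu_score(empty, ds)
        delta_from_other = bdeu_score(
            NetworkStructure(
                nodes, frozenset({("v_site", "v_type"), ("v_age", "v_days")}), tiers
            ),
            ds,
        ) - bdeu_score(other, ds)
        assert delta_from_other == pytest.approx(delta_from_empty, abs=1e-9)

    def test_strong_dependence_beats_empty(self):
        rng = np.random.default_rng(12)
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0")},
            {("A", "B")},
            {"A": [[0.5, 0.5]], "B": [[0.9, 0.1], [0.1, 0.9]]},
        )
        ds = sample_dataset(bn, 5000, seed=13)
        tiers = {"A": Tier.PERSONAL, "B": Tier.PERSONAL}
        arc = NetworkStructure(("A", "B"), frozenset({("A", "B")}), tiers)
        empty = NetworkStructure(("A", "B"), frozenset(), tiers)
        assert bdeu_score(arc, ds) > bdeu_score(empty, ds)

    def test_record_order_invariance(self, five_node_bn):
        ds = sample_dataset(five_node_bn, 300, seed=21)
        shuffled = Dataset(
            ds.schema,
            [ds.records[i] for i in np.random.default_rng(0).permutation(len(ds))],
        )
        s = NetworkStructure(
            tuple(ds.variable_names),
            frozenset({("v_site", "v_type")}),
            {v.name: v.tier for v in ds.schema},
        )
        assert bdeu_score(s, ds) == pytest.approx(bdeu_score(s, shuffled), abs=1e-9)

    def test_missing_data_rejected(self):
        ds = Dataset(_toy_schema(), [{"A": "a1", "B": MISSING}])
        with pytest.raises(ConfigurationError):
            bdeu_score(_ab_structure(), ds)


def _all_three_node_dags(nodes):
    pairs = list(itertools.permutations(nodes, 2))
    for mask in range(2 ** len(pairs)):
        arcs = {p for i, p in enumerate(pairs) if mask >> i & 1}
        if any((v, u) in arcs for u, v in arcs):
            continue
        try:
            yield NetworkStructure(
                tuple(nodes), frozenset(arcs), {n: Tier.PERSONAL for n in nodes}
            )
        except ConfigurationError:
            continue


class TestBayesianSearch:
    def test_all_arcs_forbidden_returns_forced_skeleton(self, five_node_bn):
        ds = sample_dataset(five_node_bn, 500, seed=2)
        nodes = ds.variable_names
        forbidden = {(u, v) for u in nodes for v in nodes if u != v} - {
            ("v_days", "v_sev")
        }
        st = bayesian_search(
            ds,
            forced_arcs={("v_days", "v_sev")},
            forbidden_arcs=forbidden,
            config=LearningConfig(restarts=2, seed=0),
            frozen_children=set(),
        )
        assert st.arcs == frozenset({("v_days", "v_sev")})

    def test_forced_arc_tier_violation_is_configuration_error(self, five_node_bn):
        ds = sample_dataset(five_node_bn, 50, seed=2)
        with pytest.raises(ConfigurationError, match="tier"):
            bayesian_search(ds, forced_arcs={("v_sev", "v_age")})

    def test_hill_climb_finds_exhaustive_optimum_on_three_nodes(self):
        # all 25 DAGs over three variables, scored exhaustively
        bn = make_bn(
            {"A": ("a1", "a0"), "B": ("b1", "b0"), "C": ("c1", "c0")},
            {("A", "B"), ("B", "C")},
            {
                "A": [[0.65, 0.35]],
                "B": [[0.85, 0.15], [0.2, 0.8]],
                "C": [[0.9, 0.1], [0.25, 0.75]],
            },
        )
        ds = sample_dataset(bn, 4000, seed=5)
        dags = list(_all_three_node_dags(ds.variable_names))
        assert len(dags) == 25
        best = max(bdeu_score(d, ds) for d in dags)
        st = bayesian_search(
            ds, config=LearningConfig(restarts=3, seed=0), frozen_children=set()
        )
        assert bdeu_score(st, ds) == pytest.approx(best, abs=1e-6)

    def test_five_node_recovery(self, five_node_bn):
        ds = sample_dataset(five_node_bn, 20_000, seed=6)
        st = bayesian_search(
            ds,
            forced_arcs={("v_days", "v_sev")},
            config=LearningConfig(restarts=3, seed=0),
            frozen_children={"v_sev"},
        )
        assert st.arcs == five_node_bn.structure.arcs

    @pytest.mark.parametrize("seed", range(5))
    def test_constraints_always_respected(self, five_node_bn, seed):
        rng = np.random.default_rng(seed)
        ds = sample_dataset(five_node_bn, 300, seed=seed)
        nodes = ds.variable_names
        tiers = {s.name: s.tier for s in ds.schema}
        candidates = [
            (u, v) for u in nodes for v in nodes if u != v and tiers[u] <= tiers[v]
        ]
        forbidden = {
            candidates[i] for i in rng.choice(len(candidates), size=5, replace=False)
        }
        forced = {("v_days", "v_sev")} - forbidden
        config = LearningConfig(restarts=2, seed=seed, max_parents=2)
        st = bayesian_search(
            ds, forced_arcs=forced, forbidden_arcs=forbidden, config=config,
            frozen_children=set(),
        )
        assert forced <= st.arcs
        assert not (st.arcs & forbidden)
        for node in nodes:
            assert len(st.parents(node)) <= 2
        for u, v in st.arcs:
            assert tiers[u] <= tiers[v]
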