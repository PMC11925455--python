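"""Shared fixtures: hand-built toy networks and seeded random networks."""

from __future__ import annotations

import numpy as np
import pytest

from rtsbn.network import CPT, DiscreteBN, NetworkStructure
from rtsbn.schema import Tier, VariableSpec
from rtsbn.simulate import ground_truth_bn, sample_dataset


def make_bn(variables, arcs, tables, tiers=None):
    """Build a DiscreteBN from plain dicts.

    variables: {name: (state, ...)}; arcs: iterable of (u, v); tables:
    {name: row-major ndarray with parents ordered as in the declared
    variable order}.  All nodes share one tier unless ``tiers`` given.
    """
    names = tuple(variables)
    tiers = tiers or {n: Tier.PERSONAL for n in names}
    schema = tuple(VariableSpec(n, tiers[n], tuple(variables[n])) for n in names)
    structure = NetworkStructure(names, frozenset(arcs), tiers)
    by_name = {s.name: s for s in schema}
    cpts = {}
    for node in names:
        parents = structure.parents(node)
        cpts[node] = CPT(
            node,
            parents,
            by_name[node].states,
            tuple(by_name[p].cardinality for p in parents),
            np.asarray(tables[node], dtype=float),
        )
    return DiscreteBN(structure, cpts, schema)


def random_bn(rng: np.random.Generator, max_nodes: int = 8, max_states: int = 4):
    """Random DAG with Dirichlet(1) CPTs; node order is topological."""
    n = int(rng.integers(2, max_nodes + 1))
    names = tuple(f"n{i}" for i in range(n))
    cards = {name: int(rng.integers(2, max_states + 1)) for name in names}
    arcs = set()
    for j in range(1, n):
        for i in range(j):
            if rng.random() < 0.4 and sum(1 for (u, v) in arcs if v == names[j]) < 3:
                arcs.add((names[i], names[j]))
    variables = {name: tuple(f"s{k}" for k in range(cards[name])) for name in names}
    tables = {}
    tiers = {name: Tier.PERSONAL for name in names}
    schema = tuple(
        VariableSpec(name, tiers[name], variables[name]) for name in names
    )
    structure = NetworkStructure(names, frozenset(arcs), tiers)
    for node in names:
        parents = structure.parents(node)
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        tables[node] = rng.dirichlet(np.ones(cards[node]), size=q)
    return make_bn(variables, arcs, tables)


@pytest.fixture
def chain_ab():
    """A -> B with P(a1)=0.3, P(b1|a1)=0.9, P(b1|a0)=0.2 (states a1/b1 first)."""
    return make_bn(
        {"A": ("a1", "a0"), "B": ("b1", "b0")},
        {("A", "B")},
        {"A": [[0.3, 0.7]], "B": [[0.9, 0.1], [0.2, 0.8]]},
    )


@pytest.fixture(scope="session")
def canonical_bn():
    return ground_truth_bn("canonical")


@pytest.fixture(scope="session")
def canonical_sample(canonical_bn):
    """Mid-sized canonical draw shared by read-only tests."""
    return sample_dataset(canonical_bn, 4000, seed=0)
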