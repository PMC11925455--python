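"""Discrete Bayesian network: tiered DAG plus conditional probability tables.

The graph is constrained by temporal tiers (personal -> match -> injury ->
outcome): no arc may point from a later tier to an earlier one.  Arcs within
a tier are allowed as long as the graph stays acyclic.

CPT rows are ordered with parents in declared order and the *last* parent
varying fastest (C-order raveling of the parent state indices), child states
in schema order.  This fixed ordering makes serialization bit-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .errors import ConfigurationError, SchemaViolationError
from .schema import (
    SEVERITY_FROM_DAYS,
    Tier,
    VariableSpec,
    schema_by_name,
)

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class NetworkStructure:
    """Acyclic digraph over named nodes with a temporal tier per node."""

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]
    tiers: Mapping[str, Tier]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ConfigurationError("duplicate node names")
        for u, v in self.arcs:
            if u not in node_set or v not in node_set:
                raise ConfigurationError(f"arc ({u},{v}) references unknown node")
            if self.tiers[u] > self.tiers[v]:
                raise ConfigurationError(
                    f"arc {u}->{v} points from tier {self.tiers[u].name} back to "
                    f"{self.tiers[v].name}"
                )
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigurationError("structure contains a directed cycle")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in declared node order."""
        self._check(node)
        ps = {u for u, v in self.arcs if v == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        cs = {v for u, v in self.arcs if u == node}
        return tuple(n for n in self.nodes if n in cs)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_digraph()))

    def _check(self, node: str) -> None:
        if node not in self.nodes:
            raise ConfigurationError(f"unknown node {node!r}")


def d_separated(
    structure: NetworkStructure,
    x: Iterable[str],
    y: Iterable[str],
    z: Iterable[str] = (),
) -> bool:
    """Standard d-separation: every path between X and Y blocked given Z."""
    x, y, z = set(x), set(y), set(z)
    for n in x | y | z:
        structure._check(n)
    if (x & y) or (x & z) or (y & z):
        raise ConfigurationError("X, Y, Z must be disjoint")
    return nx.is_d_separator(structure.to_digraph(), x, y, z)


def markov_blanket(structure: NetworkStructure, node: str) -> set[str]:
    """Parents, children, and the children's other parents."""
    structure._check(node)
    blanket = set(structure.parents(node)) | set(structure.children(node))
    for child in structure.children(node):
        blanket |= set(structure.parents(child))
    blanket.discard(node)
    return blanket


@dataclass
class CPT:
    """Conditional probability table for one node.

    ``table`` has shape (number of parent configurations, child cardinality);
    row ``j`` corresponds to the parent-state combination whose indices ravel
    to ``j`` in C order (last parent fastest).
    """

    child: str
    parents: tuple[str, ...]
    child_states: tuple[str, ...]
    parent_cards: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.child_states = tuple(self.child_states)
        self.parent_cards = tuple(self.parent_cards)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if self.table.shape != (q, len(self.child_states)):
            raise ConfigurationError(
                f"CPT for {self.child!r}: table shape {self.table.shape} != "
                f"({q}, {len(self.child_states)})"
            )
        if np.any(self.table < -0.0) or np.any(self.table < 0):
            raise ConfigurationError(f"CPT for {self.child!r} has negative entries")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
            raise ConfigurationError(f"CPT rows for {self.child!r} do not sum to 1")

    @property
    def n_configs(self) -> int:
        return self.table.shape[0]

    def row_index(self, parent_states: Sequence[int]) -> int:
        if not self.parents:
            return 0
        return int(np.ravel_multi_index(tuple(parent_states), self.parent_cards))

    def prob(self, child_index: int, parent_states: Sequence[int] = ()) -> float:
        return float(self.table[self.row_index(parent_states), child_index])


class DiscreteBN:
    """A discrete Bayesian network over a categorical schema."""

    def __init__(
        self,
        structure: NetworkStructure,
        cpts: Mapping[str, CPT],
        schema: Sequence[VariableSpec],
    ) -> None:
        self.structure = structure
        self.schema = tuple(schema)
        self.variables = schema_by_name(self.schema)
        self.cpts = dict(cpts)
        for node in structure.nodes:
            if node not in self.variables:
                raise ConfigurationError(f"node {node!r} absent from schema")
            if node not in self.cpts:
                raise ConfigurationError(f"missing CPT for node {node!r}")
            cpt = self.cpts[node]
            if cpt.parents != structure.parents(node):
                raise ConfigurationError(
                    f"CPT parents {cpt.parents} for {node!r} != structure parents "
                    f"{structure.parents(node)}"
                )
            if cpt.child_states != self.variables[node].states:
                raise ConfigurationError(f"CPT states for {node!r} disagree with schema")
            expect_cards = tuple(
                self.variables[p].cardinality for p in cpt.parents
            )
            if cpt.parent_cards != expect_cards:
                raise ConfigurationError(f"CPT parent cards for {node!r} disagree")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.structure.nodes

    def cardinality(self, node: str) -> int:
        return self.variables[node].cardinality

    def states(self, node: str) -> tuple[str, ...]:
        return self.variables[node].states

    def state_index(self, node: str, state: str) -> int:
        return self.variables[node].state_index(state)

    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """Probability of one complete assignment (product of CPT entries).

        Evaluated in log space; exact zeros short-circuit to 0.0.
        """
        missing = [n for n in self.nodes if n not in assignment]
        if missing:
            raise ConfigurationError(f"assignment misses nodes {missing}")
        idx = {n: self.state_index(n, assignment[n]) for n in self.nodes}
        log_p = 0.0
        for node in self.nodes:
            cpt = self.cpts[node]
            p = cpt.prob(idx[node], [idx[p] for p in cpt.parents])
            if p == 0.0:
                return 0.0
            log_p += math.log(p)
        return math.exp(log_p)


def severity_mapping_cpt(schema: Sequence[VariableSpec]) -> CPT:
    """Deterministic CPT implementing the Fuller days-to-severity coarsening.

    Every row is a point mass: 1-3 days -> minimal, 4-7 -> mild, 8-14 and
    15-28 -> moderate, 29-60 and >60 -> severe.
    """
    by_name = schema_by_name(schema)
    if "days_rts" not in by_name or "severity" not in by_name:
        raise ConfigurationError("schema must contain days_rts and severity")
    days = by_name["days_rts"]
    sev = by_name["severity"]
    table = np.zeros((days.cardinality, sev.cardinality))
    for j, day_state in enumerate(days.states):
        try:
            label = SEVERITY_FROM_DAYS[day_state]
        except KeyError:
            raise ConfigurationError(
                f"no severity mapping for days_rts state {day_state!r}"
            ) from None
        table[j, sev.state_index(label)] = 1.0
    return CPT("severity", ("days_rts",), sev.states, (days.cardinality,), table)


def bmi_mapping_cpt(schema: Sequence[VariableSpec]) -> CPT:
    """Deterministic CPT deriving the BMI band from height and weight bands.

    Like the days-to-severity link, this family is definitional rather than
    learnable: a heavier-for-height player sits in a higher BMI band.
    """
    from .dataset import bmi_state_from_states

    by_name = schema_by_name(schema)
    for name in ("height", "weight", "bmi"):
        if name not in by_name:
            raise ConfigurationError(f"schema must contain {name!r}")
    height, weight, bmi = by_name["height"], by_name["weight"], by_name["bmi"]
    table = np.zeros((height.cardinality * weight.cardinality, bmi.cardinality))
    row = 0
    for h in height.states:
        for w in weight.states:
            table[row, bmi.state_index(bmi_state_from_states(h, w))] = 1.0
            row += 1
    return CPT(
        "bmi",
        ("height", "weight"),
        bmi.states,
        (height.cardinality, weight.cardinality),
        table,
    )


# ---------------------------------------------------------------------------
# serialization


def bn_to_yaml(bn: DiscreteBN) -> str:
    doc = {
        "schema": [
            {"name": s.name, "tier": s.tier.name.lower(), "states": list(s.states)}
            for s in bn.schema
        ],
        "nodes": list(bn.nodes),
        "arcs": sorted([list(a) for a in bn.structure.arcs]),
        "cpts": {
            node: {
                "parents": list(bn.cpts[node].parents),
                "rows": [[float(x) for x in row] for row in bn.cpts[node].table],
            }
            for node in bn.nodes
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def bn_from_yaml(text: str) -> DiscreteBN:
    doc = yaml.safe_load(text)
    schema = tuple(
        VariableSpec(v["name"], Tier.from_name(v["tier"]), tuple(v["states"]))
        for v in doc["schema"]
    )
    by_name = schema_by_name(schema)
    tiers = {s.name: s.tier for s in schema}
    structure = NetworkStructure(
        tuple(doc["nodes"]),
        frozenset((u, v) for u, v in doc["arcs"]),
        tiers,
    )
    cpts = {}
    for node, spec in doc["cpts"].items():
        parents = tuple(spec["parents"])
        if parents != structure.parents(node):
            raise SchemaViolationError(
                f"serialized parents for {node!r} disagree with arcs"
            )
        cpts[node] = CPT(
            node,
            parents,
            by_name[node].states,
            tuple(by_name[p].cardinality for p in parents),
            np.asarray(spec["rows"], dtype=float),
        )
    return DiscreteBN(structure, cpts, schema)


def save_bn(bn: DiscreteBN, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(bn_to_yaml(bn))


def load_bn(path) -> DiscreteBN:
    with open(path, encoding="utf-8") as fh:
        return bn_from_yaml(fh.read())
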