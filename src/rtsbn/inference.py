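"""Exact posterior inference.

Two independent routes are provided: :func:`posterior` runs variable
elimination with a min-fill ordering, and :func:`posterior_enumerate` builds
the full joint table by broadcasting the CPT factors and sums it — a
brute-force oracle used to cross-check elimination in the test-suite.

Evidence with exactly zero probability raises
:class:`~rtsbn.errors.InconsistentEvidenceError` rather than returning an
all-zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, InconsistentEvidenceError
from .network import DiscreteBN

_ENUM_GUARD = 10_000_000


@dataclass(frozen=True)
class Distribution:
    """A normalized probability vector over one variable's states."""

    variable: str
    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "states", tuple(self.states))
        if p.shape != (len(self.states),):
            raise ConfigurationError("probability vector length != number of states")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("probabilities must be >=0 and sum to 1")

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}


def map_state(d: Distribution) -> str:
    """Most probable state; ties break to the earliest state in declared order."""
    return d.states[int(np.argmax(d.probabilities))]


def check_evidence(bn: DiscreteBN, evidence: Mapping[str, str]) -> dict[str, int]:
    """Validate evidence and return it as state indices."""
    out = {}
    for node, state in evidence.items():
        if node not in bn.variables:
            raise ConfigurationError(f"unknown evidence node {node!r}")
        out[node] = bn.state_index(node, state)
    return out


@dataclass
class _Factor:
    variables: tuple[str, ...]
    values: np.ndarray  # shape = cardinalities of `variables`, aligned axis-wise

    def restrict(self, node: str, index: int) -> "_Factor":
        ax = self.variables.index(node)
        vals = np.take(self.values, index, axis=ax)
        rest = self.variables[:ax] + self.variables[ax + 1 :]
        return _Factor(rest, vals)


def _cpt_factor(bn: DiscreteBN, node: str, ev_idx: Mapping[str, int]) -> _Factor:
    cpt = bn.cpts[node]
    shape = cpt.parent_cards + (len(cpt.child_states),)
    f = _Factor(cpt.parents + (node,), cpt.table.reshape(shape))
    for v in f.variables:
        if v in ev_idx:
            f = f.restrict(v, ev_idx[v])
    return f


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    # a's variables occupy the leading axes of the product in their own order
    joint_vars = a.variables + tuple(v for v in b.variables if v not in a.variables)
    av = a.values.reshape(a.values.shape + (1,) * (len(joint_vars) - a.values.ndim))
    b_axes = [joint_vars.index(v) for v in b.variables]
    bvals = np.transpose(b.values, axes=np.argsort(b_axes))
    reshape_to = [1] * len(joint_vars)
    for pos, ax in enumerate(sorted(b_axes)):
        reshape_to[ax] = bvals.shape[pos]
    return _Factor(joint_vars, av * bvals.reshape(reshape_to))


def _sum_out(f: _Factor, node: str) -> _Factor:
    ax = f.variables.index(node)
    return _Factor(
        f.variables[:ax] + f.variables[ax + 1 :], f.values.sum(axis=ax)
    )


def _min_fill_order(scopes: list[set[str]], hidden: set[str]) -> list[str]:
    """Elimination order by min-fill on the interaction graph; ties by name."""
    adj: dict[str, set[str]] = {}
    for scope in scopes:
        for v in scope:
            adj.setdefault(v, set()).update(u for u in scope if u != v)
    for v in hidden:
        adj.setdefault(v, set())
    order: list[str] = []
    remaining = set(hidden)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = [u for u in adj[v] if u in adj]
            fill = sum(
                1
                for i in range(len(nbrs))
                for j in range(i + 1, len(nbrs))
                if nbrs[j] not in adj[nbrs[i]]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        remaining.discard(best)
        nbrs = [u for u in adj[best] if u in adj]
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                adj[nbrs[i]].add(nbrs[j])
                adj[nbrs[j]].add(nbrs[i])
        for u in nbrs:
            adj[u].discard(best)
        del adj[best]
    return order


def posterior(
    bn: DiscreteBN, target: str, evidence: Mapping[str, str] | None = None
) -> Distribution:
    """Exact P(target | evidence) by variable elimination (min-fill order)."""
    evidence = dict(evidence or {})
    if target in evidence:
        raise ConfigurationError(f"target {target!r} appears in evidence")
    if target not in bn.variables:
        raise ConfigurationError(f"unknown target {target!r}")
    ev_idx = check_evidence(bn, evidence)

    factors = [_cpt_factor(bn, node, ev_idx) for node in bn.nodes]
    hidden = {n for n in bn.nodes if n != target and n not in ev_idx}
    order = _min_fill_order([set(f.variables) for f in factors], hidden)
    for node in order:
        related = [f for f in factors if node in f.variables]
        factors = [f for f in factors if node not in f.variables]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, node))
    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f)
    # remaining scope is exactly {target} (evidence already sliced out)
    if result.variables != (target,):
        ax = result.variables.index(target)
        vals = result.values
        for i in reversed(range(vals.ndim)):
            if i != ax:
                vals = vals.sum(axis=i)
        result = _Factor((target,), vals)
    z = float(result.values.sum())
    if z == 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence!r} has zero probability"
        )
    return Distribution(target, bn.states(target), result.values / z)


def posterior_enumerate(
    bn: DiscreteBN, target: str, evidence: Mapping[str, str] | None = None
) -> Distribution:
    """Exact posterior by summing the full joint over all completions.

    Brute-force oracle: broadcasts every evidence-restricted CPT factor to
    the full tensor over the unobserved variables and sums.  Guarded to at
    most ~1e7 assignments.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ConfigurationError(f"target {target!r} appears in evidence")
    if target not in bn.variables:
        raise ConfigurationError(f"unknown target {target!r}")
    ev_idx = check_evidence(bn, evidence)

    free = [n for n in bn.nodes if n not in ev_idx]
    cards = [bn.cardinality(n) for n in free]
    if int(np.prod(cards)) > _ENUM_GUARD:
        raise ConfigurationError(
            f"enumeration over {int(np.prod(cards))} assignments exceeds guard"
        )
    axis_of = {n: i for i, n in enumerate(free)}
    joint = np.ones(cards)
    for node in bn.nodes:
        cpt = bn.cpts[node]
        vals = cpt.table.reshape(cpt.parent_cards + (len(cpt.child_states),))
        fvars = cpt.parents + (node,)
        for v in fvars:
            if v in ev_idx:
                ax = fvars.index(v)
                vals = np.take(vals, ev_idx[v], axis=ax)
                fvars = fvars[:ax] + fvars[ax + 1 :]
        shape = [1] * len(free)
        for v in fvars:
            shape[axis_of[v]] = bn.cardinality(v)
        perm = np.argsort([axis_of[v] for v in fvars])
        joint = joint * np.transpose(vals, axes=perm).reshape(shape)
    t_ax = axis_of[target]
    marg = joint.sum(axis=tuple(i for i in range(len(free)) if i != t_ax))
    z = float(marg.sum())
    if z == 0.0:
        raise InconsistentEvidenceError(f"evidence {evidence!r} has zero probability")
    return Distribution(target, bn.states(target), marg / z)
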