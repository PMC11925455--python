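"""Post-fit model interrogation.

Strength of influence scores each arc by the average distance between the
child's conditional distributions as the parent's state changes, averaged
over the configurations of the child's other parents — the quantity a
network diagram encodes as arc thickness.  Parameter sensitivity measures
how the posterior of a chosen target state responds to perturbations of
individual CPT entries under proportional co-variation, the standard
convention that keeps rows normalized; nodes whose parameters cannot reach
the target given the evidence (a d-separation argument on an auxiliary
parent) are flagged exactly zero regardless of finite-difference noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .inference import _cpt_factor, _min_fill_order, _multiply, _sum_out, posterior
from .network import DiscreteBN

DISTANCES = ("euclidean", "hellinger", "tv")


def _row_distance(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    if kind == "euclidean":
        return float(np.linalg.norm(a - b) / math.sqrt(2.0))
    if kind == "hellinger":
        return float(math.sqrt(0.5 * np.sum((np.sqrt(a) - np.sqrt(b)) ** 2)))
    if kind == "tv":
        return float(0.5 * np.sum(np.abs(a - b)))
    raise ConfigurationError(f"unknown distance kind {kind!r}")


def joint_marginal(bn: DiscreteBN, variables: Sequence[str]) -> np.ndarray:
    """Joint marginal over ``variables`` (axes in the given order)."""
    variables = tuple(variables)
    for v in variables:
        if v not in bn.variables:
            raise ConfigurationError(f"unknown node {v!r}")
    factors = [_cpt_factor(bn, node, {}) for node in bn.nodes]
    hidden = {n for n in bn.nodes if n not in variables}
    for node in _min_fill_order([set(f.variables) for f in factors], hidden):
        related = [f for f in factors if node in f.variables]
        factors = [f for f in factors if node not in f.variables]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, node))
    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f)
    perm = [result.variables.index(v) for v in variables]
    return np.transpose(result.values, axes=perm)


def strength_of_influence(
    bn: DiscreteBN,
    arc: tuple[str, str],
    distance_kind: str = "euclidean",
    weighting: str = "uniform",
) -> float:
    """Normalized average influence of a parent on its child, in [0, 1].

    Average over all unordered pairs of parent states and configurations of
    the child's other parents of the distance between the child's
    conditional rows.  Euclidean distance is normalized by sqrt(2) so a
    deterministic swap between disjoint point masses scores exactly 1.
    ``weighting="joint"`` weights other-parent configurations by their joint
    marginal probability instead of uniformly.
    """
    parent, child = arc
    if arc not in bn.structure.arcs:
        raise ConfigurationError(f"arc {parent}->{child} not in network")
    if weighting not in ("uniform", "joint"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    cpt = bn.cpts[child]
    ax = cpt.parents.index(parent)
    shape = cpt.parent_cards + (len(cpt.child_states),)
    arr = np.moveaxis(cpt.table.reshape(shape), ax, 0)
    k = arr.shape[0]
    arr = arr.reshape(k, -1, len(cpt.child_states))  # (parent, other configs, child)
    n_other = arr.shape[1]

    if weighting == "joint":
        others = tuple(p for p in cpt.parents if p != parent)
        if others:
            w = joint_marginal(bn, others).reshape(-1)
            w = w / w.sum()
        else:
            w = np.ones(1)
    else:
        w = np.full(n_other, 1.0 / n_other)

    pairs = list(itertools.combinations(range(k), 2))
    total = 0.0
    for i, j in pairs:
        d = np.array(
            [_row_distance(arr[i, c], arr[j, c], distance_kind) for c in range(n_other)]
        )
        total += float(np.sum(w * d))
    return total / len(pairs)


@dataclass(frozen=True)
class SensitivityReport:
    """Finite-difference sensitivity of one posterior target-state probability."""

    target: str
    target_state: str
    evidence: Mapping[str, str]
    #: per-node max |dP/dtheta| over that node's CPT parameters
    aggregates: Mapping[str, float]
    #: nodes proven irrelevant by d-separation (aggregate exactly 0)
    zero_flagged: frozenset[str]
    #: (node, row index, child state index, derivative), unordered
    derivatives: tuple[tuple[str, int, int, float], ...] = field(default=())


def _perturbed_table(
    table: np.ndarray, row: int, k: int, delta: float
) -> np.ndarray:
    """Set entry (row, k) to theta+delta with proportional co-variation."""
    out = table.copy()
    theta = out[row, k]
    new = theta + delta
    if not (0.0 <= new <= 1.0):
        raise ConfigurationError("perturbation leaves the simplex")
    rest = 1.0 - theta
    if rest > 0:
        out[row] *= (1.0 - new) / rest
    else:  # point-mass row: spread the removed mass uniformly
        out[row] = (1.0 - new) / (table.shape[1] - 1)
    out[row, k] = new
    return out


def requisite_nodes(
    bn: DiscreteBN, target: str, evidence: Mapping[str, str]
) -> set[str]:
    """Nodes whose CPT parameters can influence P(target | evidence).

    A node's parameters matter iff an auxiliary parent attached to it is
    not d-separated from the target given the evidence nodes.
    """
    g = bn.structure.to_digraph()
    z = set(evidence)
    out = set()
    for node in bn.nodes:
        aux = f"__aux_{node}"
        g.add_edge(aux, node)
        if not nx.is_d_separator(g, {aux}, {target}, z - {aux}):
            out.add(node)
        g.remove_node(aux)
    return out


def sensitivity_to_parameters(
    bn: DiscreteBN,
    target: str,
    target_state: str,
    evidence: Mapping[str, str] | None = None,
    step: float = 1e-5,
) -> SensitivityReport:
    """Central finite-difference sensitivity of P(target=state | evidence).

    Each CPT entry is perturbed by ±step under proportional co-variation of
    the rest of its row.  Parameters of non-requisite nodes are flagged
    exactly zero without numerical differentiation.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ConfigurationError("target cannot be in evidence")
    t_idx = bn.state_index(target, target_state)
    relevant = requisite_nodes(bn, target, evidence)
    aggregates: dict[str, float] = {}
    zero_flagged = set()
    derivs: list[tuple[str, int, int, float]] = []
    base_cpts = dict(bn.cpts)
    for node in bn.nodes:
        if node not in relevant:
            aggregates[node] = 0.0
            zero_flagged.add(node)
            continue
        cpt = bn.cpts[node]
        best = 0.0
        for row in range(cpt.table.shape[0]):
            for k in range(cpt.table.shape[1]):
                theta = cpt.table[row, k]
                h = min(step, theta, 1.0 - theta)
                if h <= 0:
                    # entry pinned at 0 or 1: one-sided difference
                    h = step
                    deltas = (h, 0.0) if theta < 0.5 else (0.0, -h)
                else:
                    deltas = (h, -h)
                ps = []
                for delta in deltas:
                    if delta == 0.0:
                        p = posterior(bn, target, evidence).probabilities[t_idx]
                    else:
                        table = _perturbed_table(cpt.table, row, k, delta)
                        bn.cpts[node] = _replace_table(cpt, table)
                        p = posterior(bn, target, evidence).probabilities[t_idx]
                        bn.cpts[node] = base_cpts[node]
                    ps.append(float(p))
                d = (ps[0] - ps[1]) / (deltas[0] - deltas[1])
                derivs.append((node, row, k, d))
                best = max(best, abs(d))
        aggregates[node] = best
    return SensitivityReport(
        target,
        target_state,
        evidence,
        aggregates,
        frozenset(zero_flagged),
        tuple(derivs),
    )


def _replace_table(cpt, table):
    from .network import CPT

    return CPT(cpt.child, cpt.parents, cpt.child_states, cpt.parent_cards, table)


def influential_node_set(
    report: SensitivityReport, threshold: float = 0.0
) -> tuple[set[str], set[str]]:
    """Partition nodes into influential ("red") and non-influential ("grey").

    Nodes d-separated from the target given the evidence are always
    non-influential, regardless of numerical noise.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    influential = {
        n
        for n, a in report.aggregates.items()
        if a > threshold and n not in report.zero_flagged and n != report.target
    }
    grey = set(report.aggregates) - influential - {report.target}
    return influential, grey


def tornado_data(
    bn: DiscreteBN,
    target: str,
    target_state: str,
    evidence: Mapping[str, str] | None = None,
    top_m: int = 10,
    spread: float = 0.1,
) -> list[tuple[tuple[str, int, int], float, float]]:
    """Posterior swing of the most sensitive CPT parameters.

    For the ``top_m`` parameters ranked by |derivative|, evaluates the
    posterior at parameter*(1-spread) and min(1, parameter*(1+spread))
    (proportional co-variation), and returns
    ``((node, row, state index), low posterior, high posterior)`` sorted by
    descending interval width.
    """
    if not (0 < spread < 1):
        raise ConfigurationError("spread must be in (0, 1)")
    evidence = dict(evidence or {})
    report = sensitivity_to_parameters(bn, target, target_state, evidence)
    ranked = sorted(report.derivatives, key=lambda t: -abs(t[3]))[:top_m]
    t_idx = bn.state_index(target, target_state)
    out = []
    base_cpts = dict(bn.cpts)
    for node, row, k, _ in ranked:
        cpt = bn.cpts[node]
        theta = float(cpt.table[row, k])
        vals = []
        for new in (theta * (1 - spread), min(1.0, theta * (1 + spread))):
            table = _perturbed_table(cpt.table, row, k, new - theta)
            bn.cpts[node] = _replace_table(cpt, table)
            vals.append(
                float(posterior(bn, target, evidence).probabilities[t_idx])
            )
            bn.cpts[node] = base_cpts[node]
        lo, hi = sorted(vals)
        out.append(((node, row, k), lo, hi))
    out.sort(key=lambda t: -(t[2] - t[1]))
    return out
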