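"""Parameter and structure learning.

Parameters: maximum likelihood with optional Dirichlet (pseudocount)
smoothing on complete data, and expectation-maximization under
missing-at-random entries.  Structure: score-based hill-climbing over
add/delete/reverse arc moves with a BDeu score, constrained by temporal
tiers, forced and forbidden arcs, and a parent-count cap.

The deterministic days-to-RTS -> severity mapping is clinical knowledge,
not a learnable dependency: callers keep that CPT fixed by passing it via
``fixed_cpts`` and the severity node is frozen during search by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .dataset import Dataset
from .errors import ConfigurationError, InconsistentEvidenceError
from .network import CPT, DiscreteBN, NetworkStructure
from .schema import Tier, VariableSpec


@dataclass(frozen=True)
class LearningConfig:
    """Hyperparameters for parameter and structure learning.

    pseudocount
        Dirichlet smoothing added to every CPT cell (ML and EM M-step).
    ess
        BDeu equivalent sample size.
    max_parents
        Cap on the number of parents considered during search.
    restarts
        Number of seeded hill-climbing restarts (first starts from the
        forced-arc skeleton, the rest from random constraint-respecting
        graphs).
    em_tol
        Relative log-likelihood change below which EM stops.
    """

    pseudocount: float = 1.0
    ess: float = 1.0
    max_parents: int = 4
    restarts: int = 3
    seed: int = 0
    em_tol: float = 1e-4
    em_max_iter: int = 50

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")
        for name in ("ess", "max_parents", "restarts", "em_tol", "em_max_iter"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# encoding


def encode_dataset(dataset: Dataset) -> tuple[np.ndarray, tuple[str, ...], tuple[int, ...]]:
    """Records as an (n, m) integer matrix; missing cells are -1."""
    names = dataset.variable_names
    specs = {s.name: s for s in dataset.schema}
    lookup = {
        name: {state: i for i, state in enumerate(specs[name].states)}
        for name in names
    }
    codes = np.full((len(dataset), len(names)), -1, dtype=np.int32)
    for i, rec in enumerate(dataset.records):
        for j, name in enumerate(names):
            val = rec.get(name)
            if val in lookup[name]:
                codes[i, j] = lookup[name][val]
    cards = tuple(specs[n].cardinality for n in names)
    return codes, names, cards


def _family_counts(
    codes: np.ndarray,
    child: int,
    parents: Sequence[int],
    cards: Sequence[int],
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """(q, r) count matrix for one family on complete-data codes."""
    r = cards[child]
    if parents:
        pcards = [cards[p] for p in parents]
        cfg = np.ravel_multi_index(tuple(codes[:, p] for p in parents), pcards)
        q = int(np.prod(pcards))
    else:
        cfg = np.zeros(len(codes), dtype=np.int64)
        q = 1
    flat = np.bincount(cfg * r + codes[:, child], weights=weights, minlength=q * r)
    return flat.reshape(q, r).astype(float)


def _table_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    smoothed = counts + pseudocount
    tot = smoothed.sum(axis=1, keepdims=True)
    table = np.where(tot > 0, smoothed / np.where(tot == 0, 1.0, tot), 0.0)
    empty = tot[:, 0] == 0
    if np.any(empty):  # unseen configuration with no prior: uniform row
        table[empty] = 1.0 / counts.shape[1]
    return table


def _make_cpt(
    node: str,
    parents: tuple[str, ...],
    schema: Mapping[str, VariableSpec],
    table: np.ndarray,
) -> CPT:
    return CPT(
        node,
        parents,
        schema[node].states,
        tuple(schema[p].cardinality for p in parents),
        table,
    )


# ---------------------------------------------------------------------------
# maximum likelihood


def fit_parameters_ml(
    structure: NetworkStructure,
    dataset: Dataset,
    pseudocount: float = 0.0,
    fixed_cpts: Mapping[str, CPT] | None = None,
) -> dict[str, CPT]:
    """Smoothed ML estimate of every CPT from complete data.

    Each cell is (count + pseudocount) / (row total + pseudocount * r).
    Raises on missing values — use :func:`fit_parameters_em` instead.
    """
    fixed_cpts = dict(fixed_cpts or {})
    codes, names, cards = encode_dataset(dataset)
    if np.any(codes < 0):
        raise ConfigurationError(
            "dataset contains missing values; use fit_parameters_em"
        )
    col = {n: j for j, n in enumerate(names)}
    schema = {s.name: s for s in dataset.schema}
    cpts: dict[str, CPT] = {}
    for node in structure.nodes:
        if node in fixed_cpts:
            cpts[node] = fixed_cpts[node]
            continue
        parents = structure.parents(node)
        counts = _family_counts(codes, col[node], [col[p] for p in parents], cards)
        cpts[node] = _make_cpt(node, parents, schema, _table_from_counts(counts, pseudocount))
    return cpts


# ---------------------------------------------------------------------------
# expectation-maximization


def _log_tables(tables: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for k, t in tables.items():
        lt = np.full_like(t, -np.inf)
        np.log(t, out=lt, where=t > 0)
        out[k] = lt
    return out


def fit_parameters_em(
    structure: NetworkStructure,
    dataset: Dataset,
    config: LearningConfig | None = None,
    fixed_cpts: Mapping[str, CPT] | None = None,
) -> tuple[dict[str, CPT], list[float]]:
    """EM estimate of the CPTs under missing data.

    Returns the CPTs and the observed-data log-likelihood trace (one entry
    per iteration, evaluated at the parameters entering that iteration;
    non-decreasing up to the smoothing prior).  Initialization is a seeded
    Dirichlet(1) draw per CPT row.
    """
    config = config or LearningConfig()
    fixed_cpts = dict(fixed_cpts or {})
    codes, names, cards = encode_dataset(dataset)
    if len(codes) == 0:
        raise ConfigurationError("cannot fit parameters on an empty dataset")
    for j, name in enumerate(names):
        if np.all(codes[:, j] < 0):
            raise ConfigurationError(f"variable {name!r} is missing in every record")
    col = {n: j for j, n in enumerate(names)}
    schema = {s.name: s for s in dataset.schema}
    rng = np.random.default_rng(config.seed)

    families: dict[str, tuple[int, list[int], int, int]] = {}
    tables: dict[str, np.ndarray] = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        pcols = [col[p] for p in parents]
        q = int(np.prod([cards[c] for c in pcols])) if pcols else 1
        r = cards[col[node]]
        families[node] = (col[node], pcols, q, r)
        if node in fixed_cpts:
            tables[node] = np.asarray(fixed_cpts[node].table, dtype=float)
        else:
            tables[node] = rng.dirichlet(np.ones(r), size=q)

    miss = codes < 0
    pattern_ids, pattern_inverse = np.unique(miss, axis=0, return_inverse=True)
    groups = [np.flatnonzero(pattern_inverse == g) for g in range(len(pattern_ids))]

    def family_cells(node: str, values: Mapping[int, np.ndarray]):
        """Flat (config*r + child) cell index array for one family."""
        c, pcols, q, r = families[node]
        cell = values[c].astype(np.int64).copy()
        stride = r
        for p in reversed(pcols):
            cell = cell + values[p] * stride
            stride *= cards[p]
        return cell, q * r

    trace: list[float] = []
    cpts_out: dict[str, CPT] = {}
    for _ in range(config.em_max_iter):
        log_t = _log_tables(tables)
        counts = {n: np.zeros(families[n][2] * families[n][3]) for n in structure.nodes}
        loglik = 0.0
        for g, rows in enumerate(groups):
            missing_cols = np.flatnonzero(pattern_ids[g])
            if missing_cols.size == 0:
                values = {j: codes[rows, j] for j in range(len(names))}
                lp = np.zeros(len(rows))
                for node in structure.nodes:
                    cell, _ = family_cells(node, values)
                    lp += log_t[node].ravel()[cell]
                if np.any(np.isneginf(lp)):
                    raise InconsistentEvidenceError(
                        "a complete record has zero probability under the "
                        "fixed CPTs"
                    )
                loglik += float(lp.sum())
                for node in structure.nodes:
                    cell, size = family_cells(node, values)
                    counts[node] += np.bincount(cell, minlength=size)
                continue
            # enumerate completions of this missingness pattern
            mesh = np.indices([cards[j] for j in missing_cols]).reshape(
                len(missing_cols), -1
            )
            values = {}
            for j in range(len(names)):
                if j in missing_cols:
                    values[j] = mesh[list(missing_cols).index(j)][None, :]
                else:
                    values[j] = codes[rows, j][:, None]
            lp = np.zeros((len(rows), mesh.shape[1]))
            for node in structure.nodes:
                cell, _ = family_cells(node, values)
                lp = lp + log_t[node].ravel()[cell]
            z = logsumexp(lp, axis=1)
            if np.any(np.isneginf(z)):
                raise InconsistentEvidenceError(
                    "a record is impossible under the fixed CPTs for every "
                    "completion of its missing values"
                )
            loglik += float(z.sum())
            w = np.exp(lp - z[:, None])
            for node in structure.nodes:
                cell, size = family_cells(node, values)
                cell_b = np.broadcast_to(cell, w.shape)
                counts[node] += np.bincount(
                    cell_b.ravel(), weights=w.ravel(), minlength=size
                )
        trace.append(loglik)
        for node in structure.nodes:
            if node in fixed_cpts:
                continue
            _, _, q, r = families[node]
            tables[node] = _table_from_counts(
                counts[node].reshape(q, r), config.pseudocount
            )
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) < config.em_tol * max(1.0, abs(prev)):
                break

    for node in structure.nodes:
        parents = structure.parents(node)
        if node in fixed_cpts:
            cpts_out[node] = fixed_cpts[node]
        else:
            cpts_out[node] = _make_cpt(node, parents, schema, tables[node])
    return cpts_out, trace


# ---------------------------------------------------------------------------
# BDeu score and structure search


def _family_bdeu(counts: np.ndarray, ess: float) -> float:
    q, r = counts.shape
    a_jk = ess / (q * r)
    a_j = ess / q
    n_j = counts.sum(axis=1)
    score = float(np.sum(gammaln(a_j) - gammaln(a_j + n_j)))
    score += float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    return score


def bdeu_score(
    structure: NetworkStructure, dataset: Dataset, ess: float = 1.0
) -> float:
    """Decomposable BDeu log marginal likelihood (uniform structure prior)."""
    codes, names, cards = encode_dataset(dataset)
    if np.any(codes < 0):
        raise ConfigurationError("BDeu requires complete data")
    col = {n: j for j, n in enumerate(names)}
    total = 0.0
    for node in structure.nodes:
        parents = structure.parents(node)
        counts = _family_counts(codes, col[node], [col[p] for p in parents], cards)
        total += _family_bdeu(counts, ess)
    return total


class _Searcher:
    """Hill-climbing state: arc set, family-score cache, constraint checks."""

    def __init__(self, codes, names, cards, tiers, forced, forbidden, frozen, config):
        self.codes = codes
        self.names = tuple(names)
        self.cards = cards
        self.col = {n: j for j, n in enumerate(names)}
        self.tiers = tiers
        self.forced = set(forced)
        self.forbidden = set(forbidden)
        self.frozen = set(frozen)
        self.config = config
        self.cache: dict[tuple[str, frozenset], float] = {}

    def family_score(self, child: str, parents: frozenset) -> float:
        key = (child, parents)
        if key not in self.cache:
            pcols = [self.col[p] for p in self.names if p in parents]
            counts = _family_counts(self.codes, self.col[child], pcols, self.cards)
            self.cache[key] = _family_bdeu(counts, self.config.ess)
        return self.cache[key]

    def allowed_add(self, u: str, v: str, parents: dict, g: nx.DiGraph) -> bool:
        return (
            u != v
            and (u, v) not in self.forbidden
            and v not in self.frozen
            and self.tiers[u] <= self.tiers[v]
            and (u, v) not in g.edges
            and len(parents[v]) < self.config.max_parents
            and not nx.has_path(g, v, u)
        )

    def climb(self, initial_arcs: set) -> tuple[float, set]:
        parents: dict[str, set] = {n: set() for n in self.names}
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for u, v in sorted(initial_arcs):
            parents[v].add(u)
            g.add_edge(u, v)
        score = {
            n: self.family_score(n, frozenset(parents[n])) for n in self.names
        }
        while True:
            best_delta, best_move = 1e-9, None
            for v in self.names:
                if v in self.frozen:
                    continue
                for u in self.names:
                    if self.allowed_add(u, v, parents, g):
                        d = (
                            self.family_score(v, frozenset(parents[v] | {u}))
                            - score[v]
                        )
                        if d > best_delta:
                            best_delta, best_move = d, ("add", u, v)
            for u, v in sorted(g.edges):
                if (u, v) in self.forced or v in self.frozen:
                    continue
                d = self.family_score(v, frozenset(parents[v] - {u})) - score[v]
                if d > best_delta:
                    best_delta, best_move = d, ("del", u, v)
                # reverse: delete u->v then add v->u
                if (
                    u not in self.frozen
                    and (v, u) not in self.forbidden
                    and self.tiers[v] <= self.tiers[u]
                    and len(parents[u]) < self.config.max_parents
                ):
                    g.remove_edge(u, v)
                    ok = not nx.has_path(g, u, v)
                    g.add_edge(u, v)
                    if ok:
                        d = (
                            self.family_score(v, frozenset(parents[v] - {u}))
                            - score[v]
                            + self.family_score(u, frozenset(parents[u] | {v}))
                            - score[u]
                        )
                        if d > best_delta:
                            best_delta, best_move = d, ("rev", u, v)
            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                parents[v].add(u)
                g.add_edge(u, v)
            elif kind == "del":
                parents[v].discard(u)
                g.remove_edge(u, v)
            else:
                parents[v].discard(u)
                g.remove_edge(u, v)
                parents[u].add(v)
                g.add_edge(v, u)
            for n in (u, v):
                score[n] = self.family_score(n, frozenset(parents[n]))
        return sum(score.values()), set(g.edges)


def bayesian_search(
    dataset: Dataset,
    tiers: Mapping[str, Tier] | None = None,
    forced_arcs: Iterable[tuple[str, str]] = (),
    forbidden_arcs: Iterable[tuple[str, str]] = (),
    config: LearningConfig | None = None,
    frozen_children: Iterable[str] | None = None,
) -> NetworkStructure:
    """Constrained score-based structure search.

    Hill-climbing over add/delete/reverse moves from the forced-arc
    skeleton, best of ``config.restarts`` seeded restarts.  ``tiers``
    defaults to the dataset schema's tiers.  Children listed in
    ``frozen_children`` (default: ``severity`` when present) keep exactly
    their forced parents: the days-to-severity link is definitional and
    must not be re-learned.
    """
    config = config or LearningConfig()
    codes, names, cards = encode_dataset(dataset)
    if np.any(codes < 0):
        raise ConfigurationError(
            "structure search needs complete records (apply listwise deletion)"
        )
    if tiers is None:
        tiers = {s.name: s.tier for s in dataset.schema}
    if frozen_children is None:
        frozen_children = {"severity"} & set(names)
    forced = set(forced_arcs)
    forbidden = set(forbidden_arcs)
    for u, v in forced:
        if u not in names or v not in names:
            raise ConfigurationError(f"forced arc ({u},{v}) references unknown node")
        if tiers[u] > tiers[v]:
            raise ConfigurationError(f"forced arc {u}->{v} violates tier order")
        if (u, v) in forbidden:
            raise ConfigurationError(f"arc {u}->{v} both forced and forbidden")
    base = nx.DiGraph()
    base.add_nodes_from(names)
    base.add_edges_from(forced)
    if not nx.is_directed_acyclic_graph(base):
        raise ConfigurationError("forced arcs contain a cycle")

    searcher = _Searcher(
        codes, names, cards, tiers, forced, forbidden, frozen_children, config
    )
    best: tuple[float, set] | None = None
    for restart in range(config.restarts):
        arcs = set(forced)
        if restart > 0:
            rng = np.random.default_rng((config.seed + 7919 * restart) % 2**31)
            g = nx.DiGraph()
            g.add_nodes_from(names)
            g.add_edges_from(arcs)
            parents = {n: {u for u, v in arcs if v == n} for n in names}
            candidates = [
                (u, v)
                for u in names
                for v in names
                if u != v and tiers[u] <= tiers[v]
            ]
            rng.shuffle(candidates)
            for u, v in candidates:
                if rng.random() < 0.25 and searcher.allowed_add(u, v, parents, g):
                    arcs.add((u, v))
                    parents[v].add(u)
                    g.add_edge(u, v)
        score, found = searcher.climb(arcs)
        if best is None or score > best[0] + 1e-9:
            best = (score, found)
    return NetworkStructure(tuple(names), frozenset(best[1]), dict(tiers))


def structure_to_bn(
    structure: NetworkStructure,
    dataset: Dataset,
    config: LearningConfig | None = None,
    fixed_cpts: Mapping[str, CPT] | None = None,
) -> DiscreteBN:
    """Fit parameters (ML if complete, else EM) and assemble a network."""
    config = config or LearningConfig()
    if dataset.has_missing():
        cpts, _ = fit_parameters_em(structure, dataset, config, fixed_cpts)
    else:
        cpts = fit_parameters_ml(structure, dataset, config.pseudocount, fixed_cpts)
    return DiscreteBN(structure, cpts, dataset.schema)
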