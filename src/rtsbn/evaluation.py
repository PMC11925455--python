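"""Ten-fold cross-validation and confusion metrics.

The validation protocol keeps the network structure fixed and re-learns the
parameters on the training folds only; the deterministic days-to-severity
CPT is never re-learned.  Each held-out record is predicted as the argmax
of the exact posterior of the target given the record's other observed
variables, with the sibling outcome withheld (predicting days to RTS with
severity in evidence — or vice versa — would leak the label through the
definitional coarsening).

Per-class sensitivity is TP/(TP+FN) and user's accuracy TP/(TP+FP); the
overall row is the micro-average (pooled diagonal over total), which is
identical for both metrics by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import Dataset
from .errors import ConfigurationError
from .inference import map_state, posterior
from .learning import LearningConfig, structure_to_bn
from .network import CPT, NetworkStructure, severity_mapping_cpt

#: outcome variables that are deterministically linked and must not appear
#: in each other's prediction evidence
SIBLING_OUTCOMES = {"days_rts": "severity", "severity": "days_rts"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Truth-by-prediction count matrix (rows = true state, cols = predicted)."""

    states: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.states), len(self.states)):
            raise ConfigurationError("confusion matrix must be square over states")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ConfigurationError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ConfigurationError(f"state {state!r} not in matrix") from None

    def occurrences(self, state: str) -> int:
        return int(self.counts[self._index(state)].sum())


def class_sensitivity(cm: ConfusionMatrix, state: str) -> float:
    """TP / (TP + FN); 0 by convention when the state never occurs."""
    i = cm._index(state)
    row = cm.counts[i].sum()
    if row == 0:
        warnings.warn(f"state {state!r} never occurs; sensitivity reported as 0")
        return 0.0
    return float(cm.counts[i, i] / row)


def users_accuracy(cm: ConfusionMatrix, state: str) -> float:
    """TP / (TP + FP); 0 by convention when the state is never predicted."""
    i = cm._index(state)
    col = cm.counts[:, i].sum()
    if col == 0:
        warnings.warn(f"state {state!r} never predicted; user's accuracy reported as 0")
        return 0.0
    return float(cm.counts[i, i] / col)


def overall_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Micro-averaged (overall sensitivity, overall user's accuracy).

    Both equal pooled diagonal / total, so the pair is always identical —
    the same identity the per-target overall rows of a confusion-based
    report exhibit.
    """
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    acc = float(np.trace(cm.counts) / cm.total)
    return acc, acc


@dataclass(frozen=True)
class MetricsTable:
    """Per-state occurrence counts, sensitivity and user's accuracy."""

    target: str
    states: tuple[str, ...]
    occurrences: tuple[int, ...]
    sensitivity: tuple[float, ...]
    users_accuracy: tuple[float, ...]
    overall_sensitivity: float
    overall_users_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": s,
                "occurrences": o,
                "sensitivity": se,
                "users_accuracy": ua,
            }
            for s, o, se, ua in zip(
                self.states, self.occurrences, self.sensitivity, self.users_accuracy
            )
        ]
        rows.append(
            {
                "state": "overall",
                "occurrences": sum(self.occurrences),
                "sensitivity": self.overall_sensitivity,
                "users_accuracy": self.overall_users_accuracy,
            }
        )
        return pd.DataFrame(rows, columns=["state", "occurrences", "sensitivity", "users_accuracy"])


def metrics_table(cm: ConfusionMatrix, target: str = "") -> MetricsTable:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sens = tuple(class_sensitivity(cm, s) for s in cm.states)
        ua = tuple(users_accuracy(cm, s) for s in cm.states)
    overall = overall_metrics(cm)
    return MetricsTable(
        target,
        cm.states,
        tuple(cm.occurrences(s) for s in cm.states),
        sens,
        ua,
        overall[0],
        overall[1],
    )


def make_folds(dataset: Dataset | int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition into k near-equal folds (sizes differ by <=1)."""
    n = dataset if isinstance(dataset, int) else len(dataset)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds record count {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % k
    return folds


def cross_validate(
    structure: NetworkStructure,
    dataset: Dataset,
    target: str,
    k: int = 10,
    seed: int = 0,
    config: LearningConfig | None = None,
    *,
    include_sibling_evidence: bool = False,
    fixed_cpts: Mapping[str, CPT] | None = None,
    folds: np.ndarray | None = None,
) -> tuple[ConfusionMatrix, MetricsTable]:
    """k-fold CV with fixed structure and per-fold parameter re-learning.

    Returns the pooled confusion matrix over all held-out predictions and
    the metrics computed from it.
    """
    config = config or LearningConfig()
    if target not in dataset.variable_names:
        raise ConfigurationError(f"unknown target {target!r}")
    states = next(s for s in dataset.schema if s.name == target).states
    if any(r.is_missing(target) for r in dataset.records):
        raise ConfigurationError(f"dataset must be complete on target {target!r}")

    withheld = {target}
    if not include_sibling_evidence and target in SIBLING_OUTCOMES:
        sibling = SIBLING_OUTCOMES[target]
        if sibling in dataset.variable_names:
            withheld.add(sibling)
    if not (set(dataset.variable_names) - withheld):
        raise ConfigurationError("evidence policy leaves no observable evidence")

    if fixed_cpts is None and {"days_rts", "severity"} <= set(structure.nodes) and \
            structure.parents("severity") == ("days_rts",):
        fixed_cpts = {"severity": severity_mapping_cpt(dataset.schema)}

    if folds is None:
        folds = make_folds(dataset, k, seed)
    counts = np.zeros((len(states), len(states)), dtype=np.int64)
    for fold in range(k):
        train = Dataset(
            dataset.schema,
            [r for r, f in zip(dataset.records, folds) if f != fold],
            validate=False,
        )
        bn = structure_to_bn(structure, train, config, fixed_cpts)
        cache: dict[tuple, str] = {}
        for rec, f in zip(dataset.records, folds):
            if f != fold:
                continue
            evidence = {
                v: rec.get(v)
                for v in dataset.variable_names
                if v not in withheld and not rec.is_missing(v)
            }
            key = tuple(sorted(evidence.items()))
            if key not in cache:
                cache[key] = map_state(posterior(bn, target, evidence))
            pred = cache[key]
            counts[states.index(rec.get(target)), states.index(pred)] += 1
    cm = ConfusionMatrix(states, counts)
    return cm, metrics_table(cm, target)
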