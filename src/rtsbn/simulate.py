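"""Synthetic injury-record generator.

The real Bundesliga injury table behind the published model is not
deposited, so every pipeline stage is exercised against a stated synthetic
world: a tiered ground-truth network over the twelve schema variables whose
canonical arc set contains the dependencies the study reports (injury type,
body region, age and event type drive days to RTS; contact drives injury
type and body region; time of season drives event type and injury type;
height and weight determine the BMI band; days to RTS determines severity).

Two arcs beyond that reported minimum — main_position -> body_region and
age -> training_match — are part of the canonical truth.  They are
epidemiologically reasonable (goalkeepers injure the hand/wrist/shoulder
far more than outfield players; training exposure shifts with age) and they
make every arc of the DAG compelled, i.e. the canonical graph is the unique
member of its Markov-equivalence class, so structure recovery is a
well-posed exact target rather than a tie-break.

Canonical CPTs are hand-authored with strong but non-deterministic
dependencies; the days-to-RTS rows come from a discretized severity-score
model whose mass decreases with duration, mimicking the real-world skew
toward short absences.
"""

from __future__ import annotations

import numpy as np

from .dataset import Dataset, bmi_state_from_states
from .errors import ConfigurationError
from .network import CPT, DiscreteBN, NetworkStructure, bmi_mapping_cpt, severity_mapping_cpt
from .schema import (
    AGE_STATES,
    BMI_STATES,
    BODY_REGION_STATES,
    CONTACT_STATES,
    DAYS_RTS_STATES,
    HEIGHT_STATES,
    MISSING,
    POSITION_STATES,
    TIME_SEASON_STATES,
    TRAINING_MATCH_STATES,
    TYPE_INJURY_STATES,
    WEIGHT_STATES,
    load_default_schema,
    schema_by_name,
)

#: Arc set of the canonical ground truth (days_rts -> severity included).
CANONICAL_ARCS = frozenset(
    {
        ("height", "bmi"),
        ("weight", "bmi"),
        ("age", "training_match"),
        ("time_season", "training_match"),
        ("time_season", "type_injury"),
        ("contact_noncontact", "type_injury"),
        ("contact_noncontact", "body_region"),
        ("main_position", "body_region"),
        ("age", "days_rts"),
        ("training_match", "days_rts"),
        ("type_injury", "days_rts"),
        ("body_region", "days_rts"),
        ("days_rts", "severity"),
    }
)

_ROOT_PRIORS = {
    "age": (0.35, 0.37, 0.28),
    "height": (0.30, 0.42, 0.28),
    "weight": (0.36, 0.36, 0.28),
    "main_position": (0.08, 0.34, 0.34, 0.24),
    "time_season": (0.14, 0.30, 0.26, 0.30),
    "contact_noncontact": (0.44, 0.56),
}

# probability of a match (vs training) injury
_P_MATCH_SEASON = {"preseason": 0.30, "fall": 0.78, "winter": 0.62, "spring": 0.76}
_P_MATCH_AGE = {"<24": 0.14, "24-27": 0.0, ">27": -0.22}

# injury-type profiles by contact state (order = TYPE_INJURY_STATES)
_TYPE_BASE = {
    "contact": np.array([0.10, 0.26, 0.12, 0.36, 0.08, 0.02, 0.06]),
    "non-contact": np.array([0.03, 0.24, 0.52, 0.05, 0.02, 0.06, 0.08]),
}
# seasonal multipliers keyed by (season, contact state).  The muscle/tendon
# preseason spike is a conditioning phenomenon of non-contact injuries, while
# the winter fracture rise (hard frozen ground) is a contact phenomenon; the
# interaction is what orients the collider at type_injury.
_SEASON_MUSCLE = {
    ("preseason", "contact"): 1.2,
    ("preseason", "non-contact"): 3.4,
    ("fall", "contact"): 1.0,
    ("fall", "non-contact"): 1.0,
    ("winter", "contact"): 0.8,
    ("winter", "non-contact"): 0.4,
    ("spring", "contact"): 1.0,
    ("spring", "non-contact"): 1.2,
}
_SEASON_FRACTURE = {
    ("preseason", "contact"): 0.5,
    ("preseason", "non-contact"): 0.9,
    ("fall", "contact"): 1.0,
    ("fall", "non-contact"): 1.0,
    ("winter", "contact"): 3.0,
    ("winter", "non-contact"): 1.2,
    ("spring", "contact"): 1.0,
    ("spring", "non-contact"): 1.0,
}

_REGION_BASE = np.array(
    [
        0.020,  # head/face
        0.005,  # neck/cervical spine
        0.015,  # shoulder/clavicular
        0.005,  # upper arm
        0.005,  # elbow
        0.005,  # forearm
        0.005,  # wrist
        0.020,  # hand/finger/thumb
        0.010,  # sternum/ribs/upper back
        0.010,  # abdomen
        0.040,  # lower back/pelvis/sacrum
        0.100,  # hip/groin
        0.250,  # thigh
        0.150,  # knee
        0.120,  # lower leg/achilles tendon
        0.150,  # ankle
        0.040,  # foot/toe
    ]
)
#: region profile per (position, contact) pair.  Authored jointly rather than
#: as separable position and contact multipliers: the interaction (aerial-duel
#: head injuries for defenders in contact, dive-related hand/wrist injuries
#: for goalkeepers, sprint hamstring injuries for attackers off the ball) is
#: what orients the collider at body_region.
_REGION_PROFILE = {
    ("goalkeeper", "contact"): np.array(
        [2.0, 1.2, 3.0, 2.0, 3.0, 4.0, 6.0, 10.0, 1.5, 1.0, 0.8, 0.5, 0.25, 0.7, 0.5, 0.6, 0.6]
    ),
    ("goalkeeper", "non-contact"): np.array(
        [0.3, 0.6, 1.2, 0.8, 1.0, 1.2, 1.5, 2.0, 0.8, 1.2, 1.6, 1.4, 1.0, 0.9, 0.8, 0.6, 0.6]
    ),
    ("defender", "contact"): np.array(
        [4.5, 2.5, 1.5, 1.2, 1.2, 1.2, 1.2, 1.2, 2.2, 1.2, 0.7, 0.5, 0.3, 2.0, 1.0, 1.0, 0.9]
    ),
    ("defender", "non-contact"): np.array(
        [0.3, 0.6, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.8, 1.3, 1.0, 1.4, 0.7, 1.3, 0.8, 0.9]
    ),
    ("midfield", "contact"): np.array(
        [1.0, 0.8, 1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 1.3, 1.2, 0.6, 0.5, 0.35, 1.2, 2.5, 3.2, 1.5]
    ),
    ("midfield", "non-contact"): np.array(
        [0.2, 0.5, 0.4, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.8, 1.6, 1.9, 1.4, 0.8, 0.7, 0.5, 0.7]
    ),
    ("attacker", "contact"): np.array(
        [2.0, 1.2, 2.5, 1.3, 1.3, 1.3, 1.3, 1.3, 3.0, 1.6, 0.7, 0.6, 0.3, 0.8, 0.9, 1.5, 1.2]
    ),
    ("attacker", "non-contact"): np.array(
        [0.2, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.35, 0.6, 0.9, 1.5, 2.6, 0.45, 0.8, 0.55, 0.7]
    ),
}

# severity-score model for days to RTS: higher score -> longer absence
_TYPE_EFFECT = {
    "fractures and bone stress": 2.8,
    "joint and ligament": 1.5,
    "muscles and tendon": 1.0,
    "haematoma/contusions/bruise": 0.0,
    "laceration and skin lesion": 0.0,
    "central/peripheral nervous systems": 0.7,
    "other injuries": 0.4,
}
_REGION_EFFECT = {
    "head/face": 0.0,
    "neck/cervical spine": 0.4,
    "shoulder/clavicular": 1.8,
    "upper arm": 0.6,
    "elbow": 0.6,
    "forearm": 0.5,
    "wrist": 0.4,
    "hand/finger/thumb": 0.25,
    "sternum/ribs/upper back": 0.4,
    "abdomen": 0.1,
    "lower back/pelvis/sacrum": 0.8,
    "hip/groin": 1.1,
    "thigh": 1.0,
    "knee": 3.0,
    "lower leg/achilles tendon": 1.5,
    "ankle": 1.6,
    "foot/toe": 0.8,
}
_AGE_EFFECT = {"<24": 0.0, "24-27": 0.8, ">27": 1.8}
_MATCH_EFFECT = {"match": 1.0, "training": 0.0}
_SCORE_SIGMA = 0.5
_SCORE_OFFSET = -2.6
#: baseline tilt toward short absences (most injuries are short)
_DAYS_SKEW = np.array([1.0, 0.75, 0.45, 0.28, 0.15, 0.07])


def _days_row(type_injury: str, region: str, age: str, match: str) -> np.ndarray:
    score = (
        _TYPE_EFFECT[type_injury]
        + _REGION_EFFECT[region]
        + _AGE_EFFECT[age]
        + _MATCH_EFFECT[match]
        + _SCORE_OFFSET
    )
    k = np.arange(len(DAYS_RTS_STATES))
    w = _DAYS_SKEW * np.exp(-((k - score) ** 2) / (2 * _SCORE_SIGMA**2))
    return w / w.sum()


def _canonical_cpts(structure: NetworkStructure) -> dict[str, CPT]:
    schema = schema_by_name(load_default_schema())

    def cpt(node: str, table: np.ndarray) -> CPT:
        parents = structure.parents(node)
        return CPT(
            node,
            parents,
            schema[node].states,
            tuple(schema[p].cardinality for p in parents),
            table,
        )

    cpts: dict[str, CPT] = {}
    for node, prior in _ROOT_PRIORS.items():
        cpts[node] = cpt(node, np.asarray(prior, dtype=float)[None, :])

    # bmi | height, weight: deterministic band lookup
    cpts["bmi"] = bmi_mapping_cpt(load_default_schema())

    # training_match | age, time_season
    rows = []
    for a in AGE_STATES:
        for s in TIME_SEASON_STATES:
            p = float(np.clip(_P_MATCH_SEASON[s] + _P_MATCH_AGE[a], 0.05, 0.95))
            rows.append([p, 1.0 - p])
    cpts["training_match"] = cpt("training_match", np.array(rows))

    # type_injury | time_season, contact_noncontact
    muscle = TYPE_INJURY_STATES.index("muscles and tendon")
    fracture = TYPE_INJURY_STATES.index("fractures and bone stress")
    rows = []
    for s in TIME_SEASON_STATES:
        for c in CONTACT_STATES:
            row = _TYPE_BASE[c].copy()
            row[muscle] *= _SEASON_MUSCLE[(s, c)]
            row[fracture] *= _SEASON_FRACTURE[(s, c)]
            rows.append(row / row.sum())
    cpts["type_injury"] = cpt("type_injury", np.array(rows))

    # body_region | main_position, contact_noncontact
    rows = []
    for p in POSITION_STATES:
        for c in CONTACT_STATES:
            row = _REGION_BASE * _REGION_PROFILE[(p, c)]
            rows.append(row / row.sum())
    cpts["body_region"] = cpt("body_region", np.array(rows))

    # days_rts | age, training_match, type_injury, body_region
    rows = []
    for a in AGE_STATES:
        for m in TRAINING_MATCH_STATES:
            for t in TYPE_INJURY_STATES:
                for r in BODY_REGION_STATES:
                    rows.append(_days_row(t, r, a, m))
    cpts["days_rts"] = cpt("days_rts", np.array(rows))

    cpts["severity"] = severity_mapping_cpt(load_default_schema())
    return cpts


def ground_truth_bn(profile: str = "canonical", seed: int = 0) -> DiscreteBN:
    """Ground-truth network used by the synthetic world.

    ``canonical``: the fixed hand-authored network described in the module
    docstring (``seed`` is ignored).  ``random``: a tier-respecting random
    DAG with Dirichlet(1) CPTs, always containing the deterministic
    days_rts -> severity link; bit-identical for identical seeds.
    """
    schema = load_default_schema()
    tiers = {s.name: s.tier for s in schema}
    nodes = tuple(s.name for s in schema)
    if profile == "canonical":
        structure = NetworkStructure(nodes, CANONICAL_ARCS, tiers)
        return DiscreteBN(structure, _canonical_cpts(structure), schema)
    if profile == "random":
        rng = np.random.default_rng(seed)
        by_name = schema_by_name(schema)
        order = {n: i for i, n in enumerate(nodes)}
        arcs = {("days_rts", "severity")}
        parent_count = {n: 0 for n in nodes}
        parent_count["severity"] = 1
        for u in nodes:
            for v in nodes:
                if u == v or v == "severity":
                    continue
                ordered_ok = tiers[u] < tiers[v] or (
                    tiers[u] == tiers[v] and order[u] < order[v]
                )
                if ordered_ok and parent_count[v] < 3 and rng.random() < 0.3:
                    arcs.add((u, v))
                    parent_count[v] += 1
        structure = NetworkStructure(nodes, frozenset(arcs), tiers)
        cpts = {}
        for node in nodes:
            if node == "severity":
                cpts[node] = severity_mapping_cpt(schema)
                continue
            parents = structure.parents(node)
            q = int(np.prod([by_name[p].cardinality for p in parents])) if parents else 1
            r = by_name[node].cardinality
            cpts[node] = CPT(
                node,
                parents,
                by_name[node].states,
                tuple(by_name[p].cardinality for p in parents),
                rng.dirichlet(np.ones(r), size=q),
            )
        return DiscreteBN(structure, cpts, schema)
    raise ConfigurationError(f"unknown profile {profile!r}")


def sample_dataset(bn: DiscreteBN, n: int, seed: int = 0) -> Dataset:
    """Ancestral sampling of ``n`` records in topological order."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = bn.structure.topological_order()
    samples: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            cfg = np.ravel_multi_index(
                tuple(samples[p] for p in cpt.parents), cpt.parent_cards
            )
        else:
            cfg = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(cpt.table, axis=1)
        u = rng.random(n)
        samples[node] = (u[:, None] > cum[cfg]).sum(axis=1)
    states = {node: bn.states(node) for node in bn.nodes}
    records = [
        {node: states[node][samples[node][i]] for node in bn.nodes}
        for i in range(n)
    ]
    return Dataset(bn.schema, records, validate=False)


def inject_missing(
    dataset: Dataset,
    rate: float,
    protected: set[str] | None = None,
    seed: int = 0,
) -> Dataset:
    """Replace cells by the missing marker independently with probability
    ``rate`` (missing completely at random), sparing ``protected`` columns."""
    if not (0 <= rate < 1):
        raise ConfigurationError("rate must be in [0, 1)")
    protected = set(protected or ())
    rng = np.random.default_rng(seed)
    names = dataset.variable_names
    mask = rng.random((len(dataset), len(names))) < rate
    records = []
    for i, rec in enumerate(dataset.records):
        vals = dict(rec.values)
        for j, name in enumerate(names):
            if mask[i, j] and name not in protected:
                vals[name] = MISSING
        records.append(vals)
    return Dataset(dataset.schema, records, validate=False)


def case_study_evidence() -> dict[str, str]:
    """The published illustrative scenario, discretized to schema states.

    A 25-year-old attacker (77 kg, 185 cm) with a non-contact ankle
    ligament sprain in preseason training.
    """
    return {
        "age": "24-27",
        "weight": "75-81",
        "height": "180-186",
        "main_position": "attacker",
        "contact_noncontact": "non-contact",
        "type_injury": "joint and ligament",
        "body_region": "ankle",
        "time_season": "preseason",
        "training_match": "training",
    }
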