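"""Variable schema for football time-loss injury records.

The twelve variables describe one time-loss injury in professional football:
who the player is (age, height, weight, BMI, playing position), the context
of the event (time of season, training vs. match), what the injury is (body
region, injury type, contact vs. non-contact) and the outcome (days to
return to sport, and its coarsening into the four Fuller severity classes).

Continuous quantities (age, height, weight, BMI, days absent) are carried as
ordered categorical states.  Printed interval labels follow the convention
``"<a"`` = (-inf, a), ``"a-b"`` = [a, b] closed on both ends, ``">b"`` =
(b, +inf); a value landing exactly on a printed boundary therefore falls in
the middle bin.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, SchemaViolationError

#: Designated missing-value token used in CSV files and record mappings.
MISSING = "NA"


class Tier(enum.IntEnum):
    """Temporal tier of a variable; arcs may never point to an earlier tier."""

    PERSONAL = 0
    MATCH = 1
    INJURY = 2
    OUTCOME_DAYS = 3
    OUTCOME_SEVERITY = 4

    @classmethod
    def from_name(cls, name: str) -> "Tier":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ConfigurationError(f"unknown tier {name!r}") from None


@dataclass(frozen=True)
class VariableSpec:
    """A named categorical variable with ordered states and a temporal tier."""

    name: str
    tier: Tier
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ConfigurationError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError(f"duplicate states in {self.name!r}")
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise SchemaViolationError(
                f"{state!r} is not a state of {self.name!r}"
            ) from None


@dataclass(frozen=True)
class Bin:
    """One discretization bin: closed on both finite ends."""

    lower: float  # -inf for an open left ray
    upper: float  # +inf for an open right ray
    label: str

    def contains(self, x: float) -> bool:
        lo_ok = x > self.lower if math.isinf(self.lower) else x >= self.lower
        hi_ok = x < self.upper if math.isinf(self.upper) else x <= self.upper
        return lo_ok and hi_ok


@dataclass(frozen=True)
class DiscretizationRule:
    """Maps a real value to the state label of the unique covering bin."""

    variable: str
    bins: tuple[Bin, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))

    def apply(self, x: float) -> str:
        if not math.isfinite(x):
            raise ValueError(f"cannot discretize non-finite value {x!r}")
        matches = [b.label for b in self.bins if b.contains(x)]
        if len(matches) != 1:  # pragma: no cover - guarded by construction
            raise ConfigurationError(
                f"rule for {self.variable!r}: {len(matches)} bins match {x}"
            )
        return matches[0]


def _ray_rule(variable: str, cuts: Sequence[float], labels: Sequence[str]) -> DiscretizationRule:
    """Three-bin rule '<a', '[a,b]', '>b' from two cut points."""
    a, b = cuts
    return DiscretizationRule(
        variable,
        (
            Bin(-math.inf, math.nextafter(a, -math.inf), labels[0]),
            Bin(a, b, labels[1]),
            Bin(math.nextafter(b, math.inf), math.inf, labels[2]),
        ),
    )


# Canonical state spaces.  Interval labels use ASCII hyphens.
AGE_STATES = ("<24", "24-27", ">27")
HEIGHT_STATES = ("<180", "180-186", ">186")
WEIGHT_STATES = ("<75", "75-81", ">81")
BMI_STATES = ("<22.8", "22.8-23.8", ">23.8")
POSITION_STATES = ("goalkeeper", "defender", "midfield", "attacker")
BODY_REGION_STATES = (
    "head/face",
    "neck/cervical spine",
    "shoulder/clavicular",
    "upper arm",
    "elbow",
    "forearm",
    "wrist",
    "hand/finger/thumb",
    "sternum/ribs/upper back",
    "abdomen",
    "lower back/pelvis/sacrum",
    "hip/groin",
    "thigh",
    "knee",
    "lower leg/achilles tendon",
    "ankle",
    "foot/toe",
)
TYPE_INJURY_STATES = (
    "fractures and bone stress",
    "joint and ligament",
    "muscles and tendon",
    "haematoma/contusions/bruise",
    "laceration and skin lesion",
    "central/peripheral nervous systems",
    "other injuries",
)
CONTACT_STATES = ("contact", "non-contact")
TRAINING_MATCH_STATES = ("match", "training")
TIME_SEASON_STATES = ("preseason", "fall", "winter", "spring")
DAYS_RTS_STATES = ("1-3", "4-7", "8-14", "15-28", "29-60", ">60")
SEVERITY_STATES = ("minimal", "mild", "moderate", "severe")

#: Fuller coarsening of absence duration into severity classes.
SEVERITY_FROM_DAYS: Mapping[str, str] = {
    "1-3": "minimal",
    "4-7": "mild",
    "8-14": "moderate",
    "15-28": "moderate",
    "29-60": "severe",
    ">60": "severe",
}

#: Synonyms accepted on input and normalized to canonical variable names.
VARIABLE_ALIASES: Mapping[str, str] = {
    "body_part": "body_region",
    "training_game": "training_match",
    "days_RTS": "days_rts",
    "contact_non contact": "contact_noncontact",
}


def canonical_variable_name(name: str) -> str:
    return VARIABLE_ALIASES.get(name, name)


def load_default_schema() -> tuple[VariableSpec, ...]:
    """The twelve-variable schema, in tier order.

    personal -> match -> injury -> outcome (days to RTS, then severity).
    """
    return (
        VariableSpec("age", Tier.PERSONAL, AGE_STATES),
        VariableSpec("height", Tier.PERSONAL, HEIGHT_STATES),
        VariableSpec("weight", Tier.PERSONAL, WEIGHT_STATES),
        VariableSpec("bmi", Tier.PERSONAL, BMI_STATES),
        VariableSpec("main_position", Tier.PERSONAL, POSITION_STATES),
        VariableSpec("time_season", Tier.MATCH, TIME_SEASON_STATES),
        VariableSpec("training_match", Tier.MATCH, TRAINING_MATCH_STATES),
        VariableSpec("type_injury", Tier.INJURY, TYPE_INJURY_STATES),
        VariableSpec("body_region", Tier.INJURY, BODY_REGION_STATES),
        VariableSpec("contact_noncontact", Tier.INJURY, CONTACT_STATES),
        VariableSpec("days_rts", Tier.OUTCOME_DAYS, DAYS_RTS_STATES),
        VariableSpec("severity", Tier.OUTCOME_SEVERITY, SEVERITY_STATES),
    )


def default_rules() -> dict[str, DiscretizationRule]:
    """Discretization rules for the continuous variables."""
    return {
        "age": _ray_rule("age", (24, 27), AGE_STATES),
        "height": _ray_rule("height", (180, 186), HEIGHT_STATES),
        "weight": _ray_rule("weight", (75, 81), WEIGHT_STATES),
        "bmi": _ray_rule("bmi", (22.8, 23.8), BMI_STATES),
        "days_rts": DiscretizationRule(
            "days_rts",
            (
                # a time-loss injury is by definition >= 1 day absent; the
                # first bin is a left ray so the rule is total on the reals
                Bin(-math.inf, 3, "1-3"),
                Bin(math.nextafter(3, math.inf), 7, "4-7"),
                Bin(math.nextafter(7, math.inf), 14, "8-14"),
                Bin(math.nextafter(14, math.inf), 28, "15-28"),
                Bin(math.nextafter(28, math.inf), 60, "29-60"),
                Bin(math.nextafter(60, math.inf), math.inf, ">60"),
            ),
        ),
    }


def discretize_value(rule: DiscretizationRule, x: float) -> str:
    """State label of the unique bin containing ``x`` (closed-interval convention)."""
    return rule.apply(x)


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2."""
    if not (weight_kg > 0 and height_cm > 0):
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def schema_by_name(schema: Iterable[VariableSpec]) -> dict[str, VariableSpec]:
    out: dict[str, VariableSpec] = {}
    for spec in schema:
        if spec.name in out:
            raise ConfigurationError(f"duplicate variable {spec.name!r} in schema")
        out[spec.name] = spec
    return out


def schema_to_yaml(schema: Sequence[VariableSpec]) -> str:
    """Serialize a schema to a plain structured-text document."""
    doc = [
        {"name": s.name, "tier": s.tier.name.lower(), "states": list(s.states)}
        for s in schema
    ]
    return yaml.safe_dump({"variables": doc}, sort_keys=False, allow_unicode=True)


def schema_from_yaml(text: str) -> tuple[VariableSpec, ...]:
    doc = yaml.safe_load(text)
    try:
        variables = doc["variables"]
    except (TypeError, KeyError):
        raise SchemaViolationError("schema document must have a 'variables' list")
    return tuple(
        VariableSpec(v["name"], Tier.from_name(v["tier"]), tuple(v["states"]))
        for v in variables
    )
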