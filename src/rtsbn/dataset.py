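"""Injury-record tables: reading, writing and validation.

A :class:`Dataset` is a schema plus a sequence of categorical records.  Files
are plain CSV with a header row of canonical variable names (synonyms such as
``body_part`` / ``training_game`` are accepted and normalized), UTF-8, with a
single configurable missing token (default ``"NA"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import schema as _schema
from .errors import SchemaViolationError
from .schema import MISSING, SEVERITY_FROM_DAYS, VariableSpec, schema_by_name


@dataclass(frozen=True)
class InjuryRecord:
    """One time-loss injury: variable name -> state label or the missing token.

    The day of injury counts as day zero, so a one-day absence already falls
    in the shortest days-to-RTS state.
    """

    values: Mapping[str, str]

    def get(self, variable: str) -> str:
        return self.values.get(variable, MISSING)

    def is_missing(self, variable: str) -> bool:
        return self.get(variable) == MISSING


@dataclass(frozen=True)
class Violation:
    record_index: int  # -1 for dataset-level problems
    variable: str
    problem: str


class Dataset:
    """A validated table of injury records under a fixed schema."""

    def __init__(
        self,
        schema: Sequence[VariableSpec],
        records: Iterable[InjuryRecord | Mapping[str, str]],
        *,
        validate: bool = True,
    ) -> None:
        self.schema = tuple(schema)
        self._by_name = schema_by_name(self.schema)
        recs = []
        for r in records:
            if not isinstance(r, InjuryRecord):
                r = InjuryRecord(dict(r))
            recs.append(r)
        self.records: tuple[InjuryRecord, ...] = tuple(recs)
        if validate:
            bad = [v for v in self.validate() if v.problem.startswith("unknown")]
            if bad:
                v = bad[0]
                raise SchemaViolationError(
                    f"record {v.record_index}, variable {v.variable!r}: {v.problem}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.schema)

    def to_frame(self) -> pd.DataFrame:
        """Records as a string DataFrame; missing cells hold the missing token."""
        cols = self.variable_names
        data = {c: [r.get(c) for r in self.records] for c in cols}
        return pd.DataFrame(data, columns=list(cols), dtype=object)

    def complete_records(self) -> "Dataset":
        """Listwise deletion: only records with no missing cell."""
        keep = [
            r
            for r in self.records
            if all(not r.is_missing(c) for c in self.variable_names)
        ]
        return Dataset(self.schema, keep, validate=False)

    def has_missing(self) -> bool:
        return any(
            r.is_missing(c) for r in self.records for c in self.variable_names
        )

    def validate(self) -> list[Violation]:
        """Full violation report.

        Reports unknown state labels, missing cells, and — when both outcome
        variables are present — records whose severity label disagrees with
        the Fuller coarsening of their days-to-RTS state.  A missing outcome
        is reported as missing, never as an inconsistency.
        """
        report: list[Violation] = []
        for i, rec in enumerate(self.records):
            for name in rec.values:
                if name not in self._by_name:
                    report.append(Violation(i, name, f"unknown variable {name!r}"))
            for spec in self.schema:
                val = rec.get(spec.name)
                if val == MISSING:
                    report.append(Violation(i, spec.name, "missing value"))
                elif val not in spec.states:
                    report.append(
                        Violation(i, spec.name, f"unknown state label {val!r}")
                    )
            days = rec.get("days_rts")
            sev = rec.get("severity")
            if days in SEVERITY_FROM_DAYS and sev != MISSING and sev != "":
                implied = SEVERITY_FROM_DAYS[days]
                if sev != implied and sev in dict.fromkeys(SEVERITY_FROM_DAYS.values()):
                    report.append(
                        Violation(
                            i,
                            "severity",
                            f"severity {sev!r} inconsistent with days_rts "
                            f"{days!r} (implies {implied!r})",
                        )
                    )
        return report

    def inconsistencies(self) -> list[Violation]:
        return [v for v in self.validate() if "inconsistent" in v.problem]


def _normalize_cell(x: object) -> str:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return MISSING
    s = str(x).strip()
    # printed interval labels sometimes carry typographic dashes
    return s.replace("–", "-").replace("—", "-") if s else MISSING


def read_dataset(
    path,
    schema: Sequence[VariableSpec],
    *,
    missing_token: str = MISSING,
    derive_bmi: bool = True,
) -> Dataset:
    """Read a CSV of state labels under ``schema``.

    Unknown columns are rejected; alias column names are normalized; a
    ``bmi`` column absent from the file is derived from the height and
    weight states via the canonical lookup when ``derive_bmi`` is set.
    Unknown state labels raise :class:`SchemaViolationError` naming the
    row, column and offending value.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [_schema.canonical_variable_name(c.strip()) for c in df.columns]
    by_name = schema_by_name(schema)
    unknown = [c for c in df.columns if c not in by_name]
    if unknown:
        raise SchemaViolationError(f"unknown columns: {unknown}")
    missing_cols = [s.name for s in schema if s.name not in df.columns]
    if derive_bmi and "bmi" in missing_cols and {"height", "weight"} <= set(df.columns):
        missing_cols.remove("bmi")
        derive = True
    else:
        derive = False
    if missing_cols:
        raise SchemaViolationError(f"missing required columns: {missing_cols}")

    records: list[dict[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec: dict[str, str] = {}
        for name, raw in zip(df.columns, row):
            cell = _normalize_cell(raw)
            if cell == missing_token:
                cell = MISSING
            if cell != MISSING and cell not in by_name[name].states:
                raise SchemaViolationError(
                    f"row {i}, column {name!r}: unknown state label {cell!r}"
                )
            rec[name] = cell
        if derive:
            rec["bmi"] = _bmi_state_from_states(rec.get("height"), rec.get("weight"))
        records.append(rec)
    return Dataset(schema, records, validate=False)


#: BMI state implied by (height state, weight state); index arithmetic on the
#: ordered 3-state spaces: heavier-for-height -> higher BMI band.
def _bmi_state_from_states(height: str | None, weight: str | None) -> str:
    if height in (None, MISSING) or weight in (None, MISSING):
        return MISSING
    hi = _schema.HEIGHT_STATES.index(height)
    wi = _schema.WEIGHT_STATES.index(weight)
    return _schema.BMI_STATES[1 + (wi > hi) - (wi < hi)]


def bmi_state_from_states(height: str, weight: str) -> str:
    """Deterministic BMI band implied by height and weight bands."""
    return _bmi_state_from_states(height, weight)


def write_dataset(dataset: Dataset, path, *, missing_token: str = MISSING) -> None:
    """Write the dataset as canonical CSV (round-trips with :func:`read_dataset`)."""
    df = dataset.to_frame()
    if missing_token != MISSING:
        df = df.replace(MISSING, missing_token)
    df.to_csv(path, index=False)


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Violation report for a dataset (see :meth:`Dataset.validate`)."""
    return dataset.validate()
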