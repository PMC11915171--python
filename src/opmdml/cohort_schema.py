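"""Patient-level cohort data model, validation and CSV I/O.

The cohort table mirrors the variables collected for oral potentially
malignant disorder (OPMD) follow-up studies: demographics, risk habits,
systemic comorbidities, lesion characteristics, oral epithelial dysplasia
(OED) status, treatment, and the malignant-transformation (MT) outcome as
an (event, time) pair in years.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

__all__ = [
    "PatientRecord",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "CohortSchemaError",
    "read_cohort_csv",
    "write_cohort_csv",
    "summarize_cohort",
    "MIN_FOLLOWUP_YEARS",
]

#: Inclusion rule: subjects need at least six months of follow-up.
MIN_FOLLOWUP_YEARS = 0.5

_TRUE_STRINGS = {"1", "true", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "no", "n"}


class CohortSchemaError(ValueError):
    """Raised when a cohort file or record does not match the schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered categorical variables, their levels, and reference levels.

    Boolean clinical flags are represented as two-level variables with
    levels ``("no", "yes")`` and reference ``"no"`` so that reference-dropped
    one-hot encoding yields a single indicator column per flag.
    """

    variables: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    reference: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise CohortSchemaError("duplicate variable names in schema")
        for v in self.variables:
            if v not in self.levels:
                raise CohortSchemaError(f"no levels declared for variable {v!r}")
            if self.reference[v] not in self.levels[v]:
                raise CohortSchemaError(
                    f"reference level {self.reference[v]!r} not among levels of {v!r}"
                )

    def subset(self, variables: Sequence[str]) -> "FeatureSchema":
        """Schema restricted to ``variables`` (order preserved)."""
        keep = tuple(v for v in self.variables if v in set(variables))
        return FeatureSchema(
            variables=keep,
            levels={v: self.levels[v] for v in keep},
            reference={v: self.reference[v] for v in keep},
        )


_BOOL = ("no", "yes")

DEFAULT_SCHEMA = FeatureSchema(
    variables=(
        "gender",
        "age_ge60",
        "habit",
        "systemic_comorbidities",
        "hypertension",
        "diabetes",
        "hepatitis",
        "gvhd",
        "previous_malignancy",
        "lesion_type",
        "subtype",
        "site",
        "ulceration",
        "treatment",
        "oed_first",
        "oed_followup",
        "oed_grade",
    ),
    levels={
        "gender": ("female", "male"),
        "age_ge60": _BOOL,
        "habit": ("nsnd", "sd"),
        "systemic_comorbidities": _BOOL,
        "hypertension": _BOOL,
        "diabetes": _BOOL,
        "hepatitis": _BOOL,
        "gvhd": _BOOL,
        "previous_malignancy": _BOOL,
        "lesion_type": ("olp", "oll"),
        "subtype": ("white", "red"),
        "site": ("buccal", "tongue", "gingiva", "others", "multiple"),
        "ulceration": _BOOL,
        "treatment": ("medical", "excision", "none"),
        "oed_first": _BOOL,
        "oed_followup": _BOOL,
        "oed_grade": ("none", "mild", "moderate", "severe"),
    },
    reference={
        "gender": "female",
        "age_ge60": "no",
        "habit": "nsnd",
        "systemic_comorbidities": "no",
        "hypertension": "no",
        "diabetes": "no",
        "hepatitis": "no",
        "gvhd": "no",
        "previous_malignancy": "no",
        "lesion_type": "olp",
        "subtype": "white",
        "site": "buccal",
        "ulceration": "no",
        "treatment": "medical",
        "oed_first": "no",
        "oed_followup": "no",
        "oed_grade": "none",
    },
)

_BOOL_VARS = frozenset(
    v for v, lv in DEFAULT_SCHEMA.levels.items() if lv == _BOOL
)


@dataclass
class PatientRecord:
    """One subject: categorical risk factors plus the MT outcome.

    ``mt_event`` is True if the lesion transformed; ``time_years`` is the
    time to transformation if so, otherwise the censoring time.
    """

    id: str
    gender: str = "female"
    age_ge60: bool = False
    habit: str = "nsnd"
    systemic_comorbidities: bool = False
    hypertension: bool = False
    diabetes: bool = False
    hepatitis: bool = False
    gvhd: bool = False
    previous_malignancy: bool = False
    lesion_type: str = "olp"
    subtype: str = "white"
    site: str = "buccal"
    ulceration: bool = False
    treatment: str = "medical"
    oed_first: bool = False
    oed_followup: bool = False
    oed_grade: str = "none"
    mt_event: bool = False
    time_years: float = MIN_FOLLOWUP_YEARS

    def __post_init__(self) -> None:
        self.validate()

    def level(self, variable: str) -> str:
        """Canonical level string of ``variable`` for this record."""
        value = getattr(self, variable)
        if variable in _BOOL_VARS:
            return "yes" if value else "no"
        return value

    def validate(self, schema: FeatureSchema = DEFAULT_SCHEMA) -> None:
        for v in schema.variables:
            if self.level(v) not in schema.levels[v]:
                raise CohortSchemaError(
                    f"record {self.id!r}: value {self.level(v)!r} not a level of {v!r}"
                )
        t = float(self.time_years)
        if not t >= MIN_FOLLOWUP_YEARS:
            raise CohortSchemaError(
                f"record {self.id!r}: time_years={t} violates the "
                f"{MIN_FOLLOWUP_YEARS}-year minimum follow-up rule"
            )
        has_flag = self.oed_first or self.oed_followup
        if (self.oed_grade != "none") != has_flag:
            raise CohortSchemaError(
                f"record {self.id!r}: oed_grade {self.oed_grade!r} inconsistent "
                f"with OED flags (first={self.oed_first}, followup={self.oed_followup})"
            )


CSV_HEADER = [
    "id", *DEFAULT_SCHEMA.variables, "mt_event", "time_years"
]


def _normalize(raw: str) -> str:
    return raw.strip().lower().replace(" ", "_").replace("-", "_")


def _parse_bool(raw: str, column: str, row: int) -> bool:
    s = _normalize(raw)
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValueError(f"row {row}: cannot parse {raw!r} as boolean {column!r}")


def read_cohort_csv(
    path, schema: FeatureSchema = DEFAULT_SCHEMA
) -> list[PatientRecord]:
    """Read a cohort CSV, normalising values to canonical level strings.

    The reader is tolerant of case and embedded spaces; it raises
    :class:`CohortSchemaError` if a schema column is missing and
    ``ValueError`` on unknown levels or malformed times (messages name the
    offending row and value).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = set(schema.variables) | {"mt_event", "time_years"}
        missing = sorted(required - set(header))
        if missing:
            raise CohortSchemaError(f"missing column(s): {', '.join(missing)}")
        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=1):
            kwargs: dict = {"id": row.get("id", str(i))}
            for v in schema.variables:
                raw = row[v]
                if v in _BOOL_VARS:
                    kwargs[v] = _parse_bool(raw, v, i)
                else:
                    val = _normalize(raw)
                    if val not in schema.levels[v]:
                        raise ValueError(
                            f"row {i}: value {raw!r} is not a level of {v!r} "
                            f"(expected one of {schema.levels[v]})"
                        )
                    kwargs[v] = val
            kwargs["mt_event"] = _parse_bool(row["mt_event"], "mt_event", i)
            try:
                t = float(row["time_years"])
            except ValueError:
                raise ValueError(
                    f"row {i}: non-numeric time_years {row['time_years']!r}"
                ) from None
            if t < 0:
                raise ValueError(f"row {i}: negative time_years {t}")
            kwargs["time_years"] = t
            records.append(PatientRecord(**kwargs))
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    """Write records to ``path`` in the canonical CSV layout (re-readable)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            r.validate()
            row = [r.id]
            for v in DEFAULT_SCHEMA.variables:
                if v in _BOOL_VARS:
                    row.append("1" if getattr(r, v) else "0")
                else:
                    row.append(getattr(r, v))
            row.append("1" if r.mt_event else "0")
            row.append(repr(float(r.time_years)))
            writer.writerow(row)


def summarize_cohort(
    records: Sequence[PatientRecord], schema: FeatureSchema = DEFAULT_SCHEMA
) -> dict:
    """Two-way level x MT-status counts and MT percentage per level.

    Returns a dict with ``n``, ``n_mt``, ``mt_rate_percent`` (3 decimals)
    and, per variable, a mapping ``level -> {"n", "mt", "no_mt",
    "mt_rate_percent"}``.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    n_mt = sum(r.mt_event for r in records)
    out: dict = {
        "n": n,
        "n_mt": n_mt,
        "mt_rate_percent": round(100.0 * n_mt / n, 3),
        "variables": {},
    }
    for v in schema.variables:
        table: dict[str, dict] = {}
        for lv in schema.levels[v]:
            table[lv] = {"n": 0, "mt": 0, "no_mt": 0, "mt_rate_percent": None}
        for r in records:
            cell = table[r.level(v)]
            cell["n"] += 1
            if r.mt_event:
                cell["mt"] += 1
            else:
                cell["no_mt"] += 1
        for lv, cell in table.items():
            if cell["n"]:
                cell["mt_rate_percent"] = round(100.0 * cell["mt"] / cell["n"], 3)
        out["variables"][v] = table
    return out
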