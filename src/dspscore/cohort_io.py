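"""Patient-record data model, CSV I/O, and the difficult-procedure outcome.

A procedure is classified *difficult* when the performer needed more than
three punctures, needed three punctures with more than six needle passes,
or handed the procedure over after the second puncture while deeming it
difficult.  A *puncture* is a fresh skin/interspace needle entry; a *pass*
is an advancement or redirection within one puncture, so ``passes >=
punctures`` always.

Cohorts travel as RFC 4180 UTF-8 CSV with a header.  Mandatory columns are
``spine_grade``, ``experience`` and ``positioning_difficulty`` (the score's
predictors); demographics and outcome columns are optional, and unknown
columns round-trip untouched via a per-record ``extras`` mapping.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "ProcedureOutcome",
    "PatientRecord",
    "Cohort",
    "CohortError",
    "classify_difficult",
    "read_cohort",
    "write_cohort",
    "summarize_marginals",
]


class CohortError(ValueError):
    """Raised for invalid records or malformed cohort files."""


@dataclass(frozen=True)
class ProcedureOutcome:
    """Puncture/pass counts and the handover flag for one procedure."""

    punctures: int
    passes: int
    handover_declared_difficult: bool = False

    def __post_init__(self) -> None:
        if self.punctures < 1:
            raise CohortError(f"punctures must be >= 1, got {self.punctures}")
        if self.passes < self.punctures:
            raise CohortError(
                f"passes ({self.passes}) < punctures ({self.punctures}): "
                "every puncture involves at least one pass"
            )


def classify_difficult(outcome: ProcedureOutcome) -> bool:
    """Apply the difficult-procedure definition to an outcome.

    True iff punctures > 3, or exactly 3 punctures with more than 6 passes,
    or the performer handed over after the second puncture and deemed the
    procedure difficult.
    """
    return (
        outcome.punctures > 3
        or (outcome.punctures == 3 and outcome.passes > 6)
        or outcome.handover_declared_difficult
    )


_SEXES = {"male", "female"}
_ASA = {"I", "II", "III", "IV"}
_URGENCY = {"elective", "emergency"}
_TLS = {"convex", "straight", "concave"}
_POSITIONS = {"sitting", "lateral"}
_EXPERIENCE = {"<=12mo", ">12mo"}


@dataclass
class PatientRecord:
    """One spinal-arachnoid puncture procedure.

    Only the score predictors (``spine_grade``, ``experience``,
    ``positioning_difficulty``) are mandatory; demographics and the outcome
    may be absent.
    """

    id: str
    spine_grade: int
    experience: str
    positioning_difficulty: bool
    age: Optional[float] = None
    sex: Optional[str] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    asa_class: Optional[str] = None
    urgency: Optional[str] = None
    tls_contour: Optional[str] = None
    spine_deformity: Optional[bool] = None
    position: Optional[str] = None
    outcome: Optional[ProcedureOutcome] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spine_grade not in (1, 2, 3, 4):
            raise CohortError(
                f"record {self.id!r}: spine_grade {self.spine_grade} not in 1-4"
            )
        if self.experience not in _EXPERIENCE:
            raise CohortError(
                f"record {self.id!r}: experience {self.experience!r} must be "
                f"one of {sorted(_EXPERIENCE)}"
            )
        for fname, value, allowed in (
            ("sex", self.sex, _SEXES),
            ("asa_class", self.asa_class, _ASA),
            ("urgency", self.urgency, _URGENCY),
            ("tls_contour", self.tls_contour, _TLS),
            ("position", self.position, _POSITIONS),
        ):
            if value is not None and value not in allowed:
                raise CohortError(
                    f"record {self.id!r}: {fname} {value!r} not in {sorted(allowed)}"
                )
        if (
            self.bmi is not None
            and self.height is not None
            and self.weight is not None
        ):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise CohortError(
                    f"record {self.id!r}: bmi {self.bmi} inconsistent with "
                    f"weight/height ({implied:.2f})"
                )

    def predictor_levels(self) -> dict[str, str]:
        """Level labels for the built-in DSP predictors."""
        return {
            "spine_grade": str(self.spine_grade),
            "experience": self.experience,
            "positioning_difficulty": (
                "present" if self.positioning_difficulty else "absent"
            ),
        }

    @property
    def difficult(self) -> Optional[bool]:
        """Outcome label, or None when no outcome was recorded."""
        return None if self.outcome is None else classify_difficult(self.outcome)


@dataclass
class Cohort:
    """A list of procedure records with unique ids."""

    records: list[PatientRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("id", "spine_grade", "experience", "positioning_difficulty")
_OPTIONAL_FLOAT = ("age", "height", "weight", "bmi")
_OPTIONAL_STR = ("sex", "asa_class", "urgency", "tls_contour", "position")
_OUTCOME_COLS = ("punctures", "passes", "handover_declared_difficult")
_KNOWN = set(_MANDATORY) | set(_OPTIONAL_FLOAT) | set(_OPTIONAL_STR) | set(
    _OUTCOME_COLS
) | {"spine_deformity"}


def _parse_bool(text: str, *, row: int, col: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no"}:
        return False
    raise CohortError(f"row {row}: {col} {text!r} is not a boolean")


def read_cohort(path: str | Path, label: str | None = None) -> Cohort:
    """Read a cohort CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortError(f"{path}: empty file (no header)")
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise CohortError(f"{path}: missing mandatory columns {missing}")
        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                records.append(_record_from_row(row, i))
            except CohortError:
                raise
            except (ValueError, KeyError) as exc:
                raise CohortError(f"{path}: row {i}: {exc}") from exc
    return Cohort(records, label if label is not None else path.stem)


def _record_from_row(row: dict, line: int) -> PatientRecord:
    def blank(col: str) -> bool:
        return row.get(col) is None or str(row[col]).strip() == ""

    try:
        grade = int(row["spine_grade"])
    except ValueError as exc:
        raise CohortError(
            f"row {line}: spine_grade {row['spine_grade']!r} is not an integer"
        ) from exc
    kwargs: dict = {
        "id": row["id"],
        "spine_grade": grade,
        "experience": row["experience"].strip(),
        "positioning_difficulty": _parse_bool(
            row["positioning_difficulty"], row=line, col="positioning_difficulty"
        ),
    }
    for col in _OPTIONAL_FLOAT:
        if not blank(col):
            kwargs[col] = float(row[col])
    for col in _OPTIONAL_STR:
        if not blank(col):
            kwargs[col] = row[col].strip()
    if not blank("spine_deformity"):
        kwargs["spine_deformity"] = _parse_bool(
            row["spine_deformity"], row=line, col="spine_deformity"
        )
    if not blank("punctures") and not blank("passes"):
        handover = False
        if not blank("handover_declared_difficult"):
            handover = _parse_bool(
                row["handover_declared_difficult"],
                row=line,
                col="handover_declared_difficult",
            )
        try:
            kwargs["outcome"] = ProcedureOutcome(
                int(row["punctures"]), int(row["passes"]), handover
            )
        except CohortError as exc:
            raise CohortError(f"row {line}: {exc}") from exc
    kwargs["extras"] = {
        k: v for k, v in row.items() if k not in _KNOWN and k is not None
    }
    try:
        return PatientRecord(**kwargs)
    except CohortError as exc:
        raise CohortError(f"row {line}: {exc}") from exc


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that ``read_cohort`` round-trips exactly."""
    path = Path(path)
    extra_cols: list[str] = []
    for r in cohort:
        for k in r.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = (
        list(_MANDATORY[:1])
        + list(_OPTIONAL_FLOAT)
        + ["sex", "asa_class", "urgency"]
        + ["spine_grade", "tls_contour", "experience", "positioning_difficulty"]
        + ["spine_deformity", "position"]
        + list(_OUTCOME_COLS)
        + extra_cols
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for r in cohort:
            row = {
                "id": r.id,
                "spine_grade": r.spine_grade,
                "experience": r.experience,
                "positioning_difficulty": str(r.positioning_difficulty).lower(),
            }
            for col in _OPTIONAL_FLOAT:
                v = getattr(r, col)
                row[col] = "" if v is None else repr(v)
            for col in _OPTIONAL_STR:
                v = getattr(r, col)
                row[col] = "" if v is None else v
            row["spine_deformity"] = (
                "" if r.spine_deformity is None else str(r.spine_deformity).lower()
            )
            if r.outcome is not None:
                row["punctures"] = r.outcome.punctures
                row["passes"] = r.outcome.passes
                row["handover_declared_difficult"] = str(
                    r.outcome.handover_declared_difficult
                ).lower()
            else:
                row["punctures"] = row["passes"] = ""
                row["handover_declared_difficult"] = ""
            row.update(r.extras)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Marginal summary
# ---------------------------------------------------------------------------

def summarize_marginals(cohort: Cohort) -> pd.DataFrame:
    """Per-outcome-group counts/percentages and continuous means +/- SD.

    Returns a tidy frame with one row per (parameter, level) for categorical
    fields — columns ``difficult_n``, ``difficult_pct``, ``easy_n``,
    ``easy_pct`` (percentages of the group, 2 decimals) — and one row per
    continuous field with ``difficult_mean``, ``difficult_sd``, ``easy_mean``,
    ``easy_sd``.  Records without an outcome are rejected.
    """
    if any(r.outcome is None for r in cohort):
        raise CohortError("summarize_marginals requires outcomes on every record")
    rows = []
    for r in cohort:
        rows.append(
            {
                "group": "difficult" if r.difficult else "easy",
                "sex": r.sex,
                "asa_class": r.asa_class,
                "urgency": r.urgency,
                "spine_grade": str(r.spine_grade),
                "tls_contour": r.tls_contour,
                "experience": r.experience,
                "positioning_difficulty": r.positioning_difficulty,
                "spine_deformity": r.spine_deformity,
                "position": r.position,
                "age": r.age,
                "height": r.height,
                "weight": r.weight,
                "bmi": r.bmi,
            }
        )
    df = pd.DataFrame(rows)
    group_n = df["group"].value_counts().to_dict()
    out: list[dict] = []
    categorical = [
        "sex", "asa_class", "urgency", "spine_grade", "tls_contour",
        "experience", "positioning_difficulty", "spine_deformity", "position",
    ]
    for param in categorical:
        sub = df[df[param].notna()]
        if sub.empty:
            continue
        counts = sub.groupby(["group", param], observed=True).size()
        for level in sorted(sub[param].astype(str).unique()):
            entry: dict = {"parameter": param, "level": level}
            for grp in ("difficult", "easy"):
                n = 0
                for (g, lv), c in counts.items():
                    if g == grp and str(lv) == level:
                        n = int(c)
                entry[f"{grp}_n"] = n
                entry[f"{grp}_pct"] = (
                    round(100.0 * n / group_n[grp], 2) if grp in group_n else 0.0
                )
            out.append(entry)
    for param in ("age", "height", "weight", "bmi"):
        sub = df[df[param].notna()]
        if sub.empty:
            continue
        entry = {"parameter": param, "level": "mean±sd"}
        for grp in ("difficult", "easy"):
            vals = sub.loc[sub["group"] == grp, param]
            entry[f"{grp}_mean"] = round(float(vals.mean()), 2) if len(vals) else None
            entry[f"{grp}_sd"] = (
                round(float(vals.std(ddof=1)), 2) if len(vals) > 1 else None
            )
        out.append(entry)
    return pd.DataFrame(out)
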