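"""Construction and application of additive clinical risk scores.

The Difficult Spinal-Arachnoid Puncture (DSP) Score is an additive integer
score over three bedside predictors of a difficult spinal-arachnoid
puncture: the palpability grade of the lumbar spine (grades 1-4), the
performer's experience (up to vs. more than 12 months), and difficulty in
positioning the patient.  The score is built mechanically from a table of
model coefficient estimates by a three-step rule:

1. keep only predictors whose ``Pr(>|z|)`` falls below a significance
   threshold (0.01 for the built-in model);
2. take each retained predictor's maximum weight as ``|estimate|`` rounded
   to the nearest integer (half away from zero);
3. orient the weights by the coefficient's sign — a negative estimate means
   the score rises with the predictor's level order, a positive estimate
   means it falls.

For the built-in DSP model this yields spine grade 0/1/2/3, positioning
difficulty absent 0 / present 3, and experience up to one year 1 / more 0,
for an aggregate range of 0-7.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CoefficientEntry",
    "ScorePredictor",
    "ScoreModel",
    "ScoreModelError",
    "build_score_from_coefficients",
    "compute_dsp_score",
    "dsp_coefficients",
    "dsp_model",
]


class ScoreModelError(ValueError):
    """Raised when a score model cannot be built or applied."""


def _round_half_away_from_zero(x: float) -> int:
    """Nearest integer with exact halves rounded away from zero.

    Python's built-in ``round`` is half-to-even; clinical weight tables use
    ordinary "nearest integer" rounding, which differs only at exact .5.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CoefficientEntry:
    """One row of a coefficient table feeding the score builder.

    Parameters
    ----------
    predictor_name:
        Name of the predictor (e.g. ``"spine_grade"``).
    estimate:
        The model coefficient (unitless).  Its magnitude sets the maximum
        weight; its sign sets the direction over the level order.
    p_value:
        The ``Pr(>|z|)`` value of the coefficient, in [0, 1].
    predictor_kind:
        ``"ordinal"`` or ``"binary"``.
    level_labels:
        Level labels in their natural order (lowest first).
    """

    predictor_name: str
    estimate: float
    p_value: float
    predictor_kind: str
    level_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "level_labels", tuple(self.level_labels))
        if not 0.0 <= self.p_value <= 1.0:
            raise ScoreModelError(
                f"{self.predictor_name}: p_value {self.p_value} outside [0, 1]"
            )
        if self.predictor_kind not in {"ordinal", "binary"}:
            raise ScoreModelError(
                f"{self.predictor_name}: predictor_kind must be 'ordinal' or "
                f"'binary', got {self.predictor_kind!r}"
            )
        if len(self.level_labels) < 2:
            raise ScoreModelError(
                f"{self.predictor_name}: at least two levels required"
            )
        if self.predictor_kind == "binary" and len(self.level_labels) != 2:
            raise ScoreModelError(
                f"{self.predictor_name}: binary predictor must have exactly "
                f"two levels, got {len(self.level_labels)}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)


@dataclass(frozen=True)
class ScorePredictor:
    """A scored predictor: ordered levels mapped to integer points."""

    name: str
    level_weights: Mapping[str, int]
    source_estimate: float
    direction: str  # "increasing_with_level" | "decreasing_with_level"

    def __post_init__(self) -> None:
        object.__setattr__(self, "level_weights", dict(self.level_weights))
        weights = list(self.level_weights.values())
        if min(weights) != 0:
            raise ScoreModelError(f"{self.name}: minimum level weight must be 0")
        if any(w < 0 for w in weights):
            raise ScoreModelError(f"{self.name}: negative weight")
        seq = list(self.level_weights.values())  # insertion order == level order
        ascending = all(a <= b for a, b in zip(seq, seq[1:]))
        descending = all(a >= b for a, b in zip(seq, seq[1:]))
        if not (ascending or descending):
            raise ScoreModelError(f"{self.name}: weights not monotone over levels")

    @property
    def max_weight(self) -> int:
        return max(self.level_weights.values())

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.level_weights)


@dataclass(frozen=True)
class ScoreModel:
    """An additive integer score over a set of predictors."""

    predictors: tuple[ScorePredictor, ...]
    significance_threshold: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ScoreModelError("duplicate predictor names")

    @property
    def min_score(self) -> int:
        return sum(min(p.level_weights.values()) for p in self.predictors)

    @property
    def max_score(self) -> int:
        return sum(p.max_weight for p in self.predictors)

    def predictor(self, name: str) -> ScorePredictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "significance_threshold": self.significance_threshold,
            "predictors": [
                {
                    "name": p.name,
                    "level_weights": dict(p.level_weights),
                    "source_estimate": p.source_estimate,
                    "direction": p.direction,
                }
                for p in self.predictors
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScoreModel":
        doc = json.loads(text)
        predictors = tuple(
            ScorePredictor(
                name=p["name"],
                level_weights={k: int(v) for k, v in p["level_weights"].items()},
                source_estimate=float(p["source_estimate"]),
                direction=p["direction"],
            )
            for p in doc["predictors"]
        )
        return cls(predictors, float(doc.get("significance_threshold", 0.01)))


def build_score_from_coefficients(
    entries: Iterable[CoefficientEntry],
    threshold: float = 0.01,
    *,
    max_weight_levels: Mapping[str, str] | None = None,
) -> ScoreModel:
    """Build an additive score model from a coefficient table.

    Entries with ``p_value >= threshold`` are dropped.  Each retained
    predictor's maximum weight is ``|estimate|`` rounded to the nearest
    integer (half away from zero).  Ordinal predictors get linear integer
    weights ``0..max`` over the level order, ascending when the estimate is
    negative and descending when positive; this is only well defined when
    ``max == n_levels - 1``, and any other case is rejected.  Binary
    predictors get ``{0, max}`` with the maximum on the level the sign
    indicates.

    Parameters
    ----------
    entries:
        Coefficient table rows.
    threshold:
        Significance threshold on ``Pr(>|z|)``; strictly-below retains.
    max_weight_levels:
        Optional explicit override, per predictor name, of the level that
        receives the maximum weight (binary predictors only).  When absent
        the coefficient's sign decides: negative puts the maximum on the
        last (highest) level, positive on the first.

    Raises
    ------
    ScoreModelError
        If no entry survives the filter, a retained weight rounds to 0, or
        an ordinal predictor's rounded weight differs from ``n_levels - 1``.
    """
    entries = list(entries)
    if not entries:
        raise ScoreModelError("empty coefficient table")
    if not 0.0 < threshold < 1.0:
        raise ScoreModelError(f"threshold {threshold} outside (0, 1)")
    overrides = dict(max_weight_levels or {})

    retained = [e for e in entries if e.p_value < threshold]
    if not retained:
        raise ScoreModelError(
            f"no predictor significant at Pr(>|z|) < {threshold}"
        )

    predictors: list[ScorePredictor] = []
    for e in retained:
        max_w = _round_half_away_from_zero(abs(e.estimate))
        if max_w == 0:
            raise ScoreModelError(
                f"{e.predictor_name}: |estimate| {abs(e.estimate)} rounds to a "
                "weight of 0 — predictor carries no points; remove it or "
                "rescale the estimates"
            )
        negative = e.estimate < 0
        direction = "increasing_with_level" if negative else "decreasing_with_level"
        if e.predictor_kind == "ordinal":
            if max_w != e.n_levels - 1:
                raise ScoreModelError(
                    f"{e.predictor_name}: rounded weight {max_w} does not match "
                    f"n_levels - 1 = {e.n_levels - 1}; the linear 0..max level "
                    "assignment is ambiguous for this predictor"
                )
            seq = range(max_w + 1) if negative else range(max_w, -1, -1)
            weights = {lvl: w for lvl, w in zip(e.level_labels, seq)}
        else:  # binary
            if e.predictor_name in overrides:
                hot = overrides[e.predictor_name]
                if hot not in e.level_labels:
                    raise ScoreModelError(
                        f"{e.predictor_name}: override level {hot!r} is not "
                        f"one of {e.level_labels}"
                    )
            else:
                hot = e.level_labels[-1] if negative else e.level_labels[0]
            weights = {lvl: (max_w if lvl == hot else 0) for lvl in e.level_labels}
        predictors.append(
            ScorePredictor(
                name=e.predictor_name,
                level_weights=weights,
                source_estimate=e.estimate,
                direction=direction,
            )
        )
    return ScoreModel(tuple(predictors), threshold)


def compute_dsp_score(record, model: ScoreModel | None = None) -> int:
    """Score a record under a model (the built-in DSP model by default).

    ``record`` is either a mapping from predictor name to level label or an
    object with a ``predictor_levels()`` method returning one (e.g.
    :class:`dspscore.cohort_io.PatientRecord`).

    Raises
    ------
    ScoreModelError
        If a predictor level is missing or not among the model's levels;
        the offending field is named.
    """
    if model is None:
        model = dsp_model()
    if hasattr(record, "predictor_levels"):
        levels = record.predictor_levels()
    else:
        levels = dict(record)
    total = 0
    for p in model.predictors:
        if p.name not in levels:
            raise ScoreModelError(f"record is missing predictor {p.name!r}")
        lvl = str(levels[p.name])
        if lvl not in p.level_weights:
            raise ScoreModelError(
                f"{p.name}: level {lvl!r} not in {tuple(p.level_weights)}"
            )
        total += p.level_weights[lvl]
    return total


# ---------------------------------------------------------------------------
# Built-in DSP model
# ---------------------------------------------------------------------------

SPINE_GRADE_LEVELS = ("1", "2", "3", "4")
EXPERIENCE_LEVELS = ("<=12mo", ">12mo")
POSITIONING_LEVELS = ("absent", "present")


def dsp_coefficients() -> list[CoefficientEntry]:
    """The published coefficient table behind the DSP Score.

    Spine grade, positioning difficulty and performer experience were the
    only predictors with Pr(>|z|) < 0.01 in the underlying network analysis
    (estimates -2.715, -2.98 and 1.045); the p-values here are recorded as
    0.009 since only the bound "< 0.01" was reported.
    """
    return [
        CoefficientEntry("spine_grade", -2.715, 0.009, "ordinal", SPINE_GRADE_LEVELS),
        CoefficientEntry("positioning_difficulty", -2.98, 0.009, "binary", POSITIONING_LEVELS),
        CoefficientEntry("experience", 1.045, 0.009, "binary", EXPERIENCE_LEVELS),
    ]


def dsp_model() -> ScoreModel:
    """The built-in DSP Score model (range 0-7), rebuilt from coefficients."""
    return build_score_from_coefficients(dsp_coefficients(), threshold=0.01)
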