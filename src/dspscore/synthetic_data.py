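"""Seeded simulation of spinal-arachnoid puncture cohorts.

The generator emulates the structure of the 300-procedure index cohort:
predictors are drawn independently from the cohort's pooled marginal
frequencies (spine grades 95/148/52/5 of 300, experience up to 12 months
196/300, positioning difficulty 12/300), and the difficult outcome is
drawn from a logistic latent model

    logit P(difficult) = b0 + b_grade*(grade - 1) + b_exp*1[<=12mo]
                         + b_pos*1[positioning difficulty]

with slope signs matching the published coefficient estimates (higher
grade, junior performer and positioning difficulty all increase risk) and
the intercept calibrated by bisection so that the expected prevalence over
the 16-cell predictor lattice equals the 18% observed in the index cohort.

Default slope magnitudes reuse the published estimates: the full
four-grade range contributes |−2.715| (0.905 per grade step), experience
contributes 1.045 and positioning difficulty 2.98 on the log-odds scale.

Puncture/pass counts are then drawn consistently with the label: easy
procedures use at most 3 punctures and at most 6 passes, difficult ones
are a mixture of many-puncture, many-pass and handover presentations.
Optional demographics (age, sex, height/weight/BMI) are drawn from simple
distributions matched to the index cohort's summary table; they carry no
signal by construction.

All randomness flows from a single ``numpy`` generator seeded by
``SimulationConfig.seed``; identical configs produce identical cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort_io import Cohort, PatientRecord, ProcedureOutcome, classify_difficult

__all__ = [
    "LatentCoefficients",
    "PredictorMarginals",
    "SimulationConfig",
    "SimulationError",
    "calibrate_intercept",
    "expected_prevalence",
    "simulate_cohort",
]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class PredictorMarginals:
    """Marginal level probabilities of the three score predictors."""

    spine_grade: tuple[float, float, float, float] = (
        95 / 300, 148 / 300, 52 / 300, 5 / 300,
    )
    experience_junior: float = 196 / 300  # P(<=12 months)
    positioning_difficulty: float = 12 / 300

    def __post_init__(self) -> None:
        if abs(sum(self.spine_grade) - 1.0) > 1e-9:
            raise SimulationError("spine_grade probabilities must sum to 1")
        if any(p < 0 for p in self.spine_grade):
            raise SimulationError("negative spine_grade probability")
        for name in ("experience_junior", "positioning_difficulty"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} probability {p} outside [0, 1]")


@dataclass(frozen=True)
class LatentCoefficients:
    """Log-odds slopes of the latent difficulty model (intercept separate)."""

    grade_step: float = 2.715 / 3  # per spine-grade increment
    experience_junior: float = 1.045
    positioning_difficulty: float = 2.98


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a simulated cohort."""

    n: int = 300
    seed: int = 0
    marginals: PredictorMarginals = field(default_factory=PredictorMarginals)
    coefficients: LatentCoefficients = field(default_factory=LatentCoefficients)
    target_prevalence: float = 0.18
    include_demographics: bool = True
    label: str = "simulated"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise SimulationError(
                f"target_prevalence {self.target_prevalence} outside (0, 1)"
            )


def _lattice(config: SimulationConfig):
    """All 16 predictor cells with probabilities and linear predictors."""
    m, b = config.marginals, config.coefficients
    cells = []
    for (gi, pg), junior, pos in itertools.product(
        enumerate(m.spine_grade), (True, False), (True, False)
    ):
        p_cell = (
            pg
            * (m.experience_junior if junior else 1 - m.experience_junior)
            * (m.positioning_difficulty if pos else 1 - m.positioning_difficulty)
        )
        eta = (
            b.grade_step * gi
            + (b.experience_junior if junior else 0.0)
            + (b.positioning_difficulty if pos else 0.0)
        )
        cells.append((p_cell, eta))
    return cells


def expected_prevalence(config: SimulationConfig, intercept: float) -> float:
    """Exact P(difficult) over the finite predictor lattice."""
    return float(
        sum(p * expit(intercept + eta) for p, eta in _lattice(config))
    )


def calibrate_intercept(config: SimulationConfig, tol: float = 1e-9) -> float:
    """Intercept at which expected prevalence equals the target.

    The expected prevalence is strictly increasing in the intercept, so
    simple root bracketing converges; the result satisfies
    ``|expected - target| < 1e-6`` by construction.
    """
    target = config.target_prevalence

    def gap(b0: float) -> float:
        return expected_prevalence(config, b0) - target

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise SimulationError(
            f"target prevalence {target} unreachable with the given coefficients"
        )
    return float(brentq(gap, lo, hi, xtol=tol))


def _draw_outcome(rng: np.random.Generator, difficult: bool) -> ProcedureOutcome:
    """Puncture/pass counts consistent with the difficulty definition."""
    if not difficult:
        punctures = int(rng.integers(1, 4))  # 1..3
        passes = int(rng.integers(punctures, 7))  # <= 6
        return ProcedureOutcome(punctures, passes, False)
    kind = rng.choice(["many_punctures", "many_passes", "handover"], p=[0.6, 0.25, 0.15])
    if kind == "many_punctures":
        punctures = int(rng.integers(4, 7))  # > 3
        passes = punctures + int(rng.integers(0, 4))
        return ProcedureOutcome(punctures, passes, False)
    if kind == "many_passes":
        passes = int(rng.integers(7, 11))  # 3 punctures, > 6 passes
        return ProcedureOutcome(3, passes, False)
    punctures = int(rng.integers(2, 4))
    passes = punctures + int(rng.integers(0, 3))
    return ProcedureOutcome(punctures, passes, True)


def _draw_demographics(rng: np.random.Generator) -> dict:
    """Covariates matched loosely to the index cohort's summary table."""
    height = float(np.clip(rng.normal(161.8, 9.3), 140.0, 195.0))
    bmi = float(np.clip(rng.normal(23.8, 5.0), 14.0, 45.0))
    weight = bmi * (height / 100.0) ** 2
    return {
        "age": round(float(np.clip(rng.normal(45.3, 16.6), 18.0, 90.0)), 1),
        "sex": "male" if rng.random() < 227 / 300 else "female",
        "height": round(height, 1),
        "weight": round(weight, 1),
        "bmi": round(bmi, 2),
        "asa_class": str(rng.choice(["I", "II", "III", "IV"], p=[76 / 300, 169 / 300, 49 / 300, 6 / 300])),
        "urgency": "elective" if rng.random() < 291 / 300 else "emergency",
        "tls_contour": str(rng.choice(["convex", "straight", "concave"], p=[152 / 300, 133 / 300, 15 / 300])),
        "spine_deformity": bool(rng.random() < 7 / 300),
        "position": "sitting" if rng.random() < 294 / 300 else "lateral",
    }


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a fully labelled cohort under the latent logistic model."""
    rng = np.random.default_rng(config.seed)
    b0 = calibrate_intercept(config)
    m, b = config.marginals, config.coefficients

    grades = rng.choice([1, 2, 3, 4], size=config.n, p=m.spine_grade)
    junior = rng.random(config.n) < m.experience_junior
    pos_diff = rng.random(config.n) < m.positioning_difficulty
    eta = (
        b0
        + b.grade_step * (grades - 1)
        + b.experience_junior * junior
        + b.positioning_difficulty * pos_diff
    )
    difficult = rng.random(config.n) < expit(eta)

    records = []
    for i in range(config.n):
        demo = _draw_demographics(rng) if config.include_demographics else {}
        outcome = _draw_outcome(rng, bool(difficult[i]))
        assert classify_difficult(outcome) == bool(difficult[i])
        records.append(
            PatientRecord(
                id=f"S{i + 1:05d}",
                spine_grade=int(grades[i]),
                experience="<=12mo" if junior[i] else ">12mo",
                positioning_difficulty=bool(pos_diff[i]),
                outcome=outcome,
                **demo,
            )
        )
    return Cohort(records, config.label)
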