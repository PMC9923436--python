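"""Discrete-score ROC curves, Youden's J, and efficiency-optimal cutoffs.

A risk score taking a handful of integer values yields one operating point
per candidate cutoff (positivity: score >= cutoff).  Candidate cutoffs are
the distinct observed scores plus one above the maximum, so the curve
always spans from (sens 1, spec 0) — everyone positive — to
(sens 0, spec 1).

The area under the ROC curve is computed by the trapezoidal rule over the
vertices (1 - spec, sens) with anchors (0, 0) and (1, 1); for integer
scores this equals the Mann-Whitney two-sample statistic with half credit
for ties.  The AUC confidence interval uses the Hanley-McNeil variance
approximation.

Two cutoff-selection rules are provided:

* Youden's J: argmax of J(c) = sens(c) + spec(c) - 1;
* efficiency at prevalence P: argmax of P*sens(c) + (1-P)*spec(c), the
  expected proportion correctly classified in a population with difficulty
  prevalence P.  At P = 0.5 the two rules coincide.

Ties in either argmax break toward the smaller cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .diagnostics import IntervalEstimate

__all__ = [
    "OperatingPoint",
    "RocCurve",
    "RocError",
    "roc_from_scores",
    "youden_optimal_cutoff",
    "efficiency_optimal_cutoff",
    "plot_roc",
]


class RocError(ValueError):
    """Raised for degenerate ROC inputs."""


@dataclass(frozen=True)
class OperatingPoint:
    """Sensitivity/specificity at one cutoff (positive: score >= cutoff)."""

    cutoff: int
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise RocError(
                f"cutoff {self.cutoff}: sensitivity/specificity outside [0, 1]"
            )

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def efficiency(self, p: float) -> float:
        return p * self.sensitivity + (1.0 - p) * self.specificity


@dataclass(frozen=True)
class RocCurve:
    """Operating points ordered by cutoff, with trapezoidal AUC."""

    points: tuple[OperatingPoint, ...]
    auc: float
    auc_ci: Optional[IntervalEstimate] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        cuts = [pt.cutoff for pt in self.points]
        if cuts != sorted(cuts):
            raise RocError("operating points must be ordered by cutoff")
        sens = [pt.sensitivity for pt in self.points]
        spec = [pt.specificity for pt in self.points]
        if any(a < b - 1e-12 for a, b in zip(sens, sens[1:])):
            raise RocError("sensitivity must be non-increasing in cutoff")
        if any(a > b + 1e-12 for a, b in zip(spec, spec[1:])):
            raise RocError("specificity must be non-decreasing in cutoff")

    def vertices(self) -> np.ndarray:
        """ROC vertices (1 - spec, sens) including the (0,0)/(1,1) anchors."""
        pts = [(1.0 - p.specificity, p.sensitivity) for p in self.points]
        pts += [(0.0, 0.0), (1.0, 1.0)]
        arr = np.array(sorted(set(pts)))
        return arr

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "cutoff": [p.cutoff for p in self.points],
                "sensitivity": [p.sensitivity for p in self.points],
                "specificity": [p.specificity for p in self.points],
            }
        ).to_csv(path, index=False)


def _trapezoid_auc(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return float(np.trapezoid(y, x))


def _hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float
) -> IntervalEstimate:
    """Hanley-McNeil variance approximation for the AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return IntervalEstimate(
        auc, max(0.0, auc - half), min(1.0, auc + half), "hanley-mcneil", level
    )


def roc_from_scores(
    scores: Sequence[int],
    labels: Sequence[bool],
    level: float = 0.95,
) -> RocCurve:
    """Assemble the discrete-score ROC curve from scores and outcome labels."""
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.size == 0:
        raise RocError("scores and labels must be equal-length and non-empty")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise RocError("both outcome classes must be present")

    pos = scores[labels]
    neg = scores[~labels]
    cutoffs = sorted(set(scores.tolist()))
    cutoffs.append(cutoffs[-1] + 1)  # all-negative operating point
    points = tuple(
        OperatingPoint(
            cutoff=int(c),
            sensitivity=float((pos >= c).mean()),
            specificity=float((neg < c).mean()),
        )
        for c in cutoffs
    )
    curve_auc = _trapezoid_auc(
        np.array(
            sorted(
                {(1.0 - p.specificity, p.sensitivity) for p in points}
                | {(0.0, 0.0), (1.0, 1.0)}
            )
        )
    )
    ci = _hanley_mcneil_ci(curve_auc, n_pos, n_neg, level)
    return RocCurve(points, curve_auc, ci)


def youden_optimal_cutoff(curve: RocCurve) -> tuple[int, float]:
    """Cutoff maximizing J = sens + spec - 1; ties go to the smaller cutoff."""
    if not curve.points:
        raise RocError("empty curve")
    best = max(curve.points, key=lambda p: (p.youden_j, -p.cutoff))
    return best.cutoff, best.youden_j


def efficiency_optimal_cutoff(curve: RocCurve, p: float) -> tuple[int, float]:
    """Cutoff maximizing P*sens + (1-P)*spec; ties go to the smaller cutoff."""
    if not 0.0 < p < 1.0:
        raise RocError(f"prevalence {p} outside (0, 1)")
    if not curve.points:
        raise RocError("empty curve")
    best = max(curve.points, key=lambda pt: (pt.efficiency(p), -pt.cutoff))
    return best.cutoff, best.efficiency(p)


def plot_roc(curve: RocCurve, path, title: str = "ROC curve") -> None:
    """Write the ROC polygon with an AUC annotation to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = curve.vertices()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(v[:, 0], v[:, 1], marker="o", color="tab:blue")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    label = f"AUC = {curve.auc:.3f}"
    if curve.auc_ci is not None:
        label += f" (95% CI {curve.auc_ci.lower:.3f}-{curve.auc_ci.upper:.3f})"
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    ax.text(0.45, 0.1, label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
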