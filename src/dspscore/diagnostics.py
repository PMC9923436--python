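"""2x2 diagnostic-test statistics with confidence intervals.

Positivity convention: a record is test-positive when its score is **at or
above** the cutoff.  All statistics derive from the 2x2 table

====================  ==========  ======
                      difficult    easy
====================  ==========  ======
score >= cutoff          tp         fp
score <  cutoff          fn         tn
====================  ==========  ======

Point estimates: sensitivity tp/(tp+fn), specificity tn/(tn+fp), likelihood
ratios PLR = sens/(1-spec) and NLR = (1-sens)/spec, and predictive values
and accuracy *adjusted to an arbitrary prevalence p* via Bayes' theorem:

    PPV = sens*p / (sens*p + (1-spec)*(1-p))
    NPV = spec*(1-p) / (spec*(1-p) + (1-sens)*p)
    accuracy = p*sens + (1-p)*spec

When p is the sample's own prevalence these reduce exactly to tp/(tp+fp),
tn/(tn+fn) and (tp+tn)/total.

Interval methods (95% default, z = 1.959964):

* sensitivity, specificity — Clopper-Pearson exact binomial;
* PLR, NLR — the log method (normal interval on the log likelihood ratio
  with variance 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn), and the fn/tn analogue
  for the NLR);
* prevalence-adjusted PPV/NPV — the logit method: a normal interval on
  logit(PV), whose variance equals the log-LR variance above since
  logit(PPV) = logit(p) + log(PLR);
* accuracy — delta method on p*sens + (1-p)*spec with independent binomial
  variances for sensitivity and specificity.

Zero cells make some ratios unbounded; these are reported as ``inf`` with
an ``unbounded`` flag rather than continuity-corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "IntervalEstimate",
    "DiagnosticReport",
    "DiagnosticsError",
    "build_two_by_two",
    "diagnostic_report",
    "clopper_pearson",
]

_Z = norm.ppf  # exact quantiles; z(0.975) = 1.959964...


class DiagnosticsError(ValueError):
    """Raised for invalid 2x2 inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: tp = difficult with score >= cutoff, etc."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("negative cell count")
        if self.total == 0:
            raise DiagnosticsError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Number of truly difficult procedures."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def sample_prevalence(self) -> float:
        return self.n_positive / self.total


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    method: str
    level: float = 0.95
    unbounded: bool = False

    def __post_init__(self) -> None:
        if not self.unbounded and not (
            math.isnan(self.point) or self.lower - 1e-12 <= self.point <= self.upper + 1e-12
        ):
            raise DiagnosticsError(
                f"interval [{self.lower}, {self.upper}] does not contain "
                f"point {self.point}"
            )


@dataclass(frozen=True)
class DiagnosticReport:
    """Full set of diagnostic statistics at a cutoff and prevalence."""

    counts: ConfusionCounts
    prevalence: float
    level: float
    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    plr: IntervalEstimate
    nlr: IntervalEstimate
    ppv: IntervalEstimate
    npv: IntervalEstimate
    accuracy: IntervalEstimate

    def to_dict(self) -> dict:
        def iv(e: IntervalEstimate) -> dict:
            return {
                "point": e.point,
                "lower": e.lower,
                "upper": e.upper,
                "method": e.method,
                "unbounded": e.unbounded,
            }

        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "prevalence": self.prevalence,
            "level": self.level,
            "sensitivity": iv(self.sensitivity),
            "specificity": iv(self.specificity),
            "plr": iv(self.plr),
            "nlr": iv(self.nlr),
            "ppv": iv(self.ppv),
            "npv": iv(self.npv),
            "accuracy": iv(self.accuracy),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Plain-text table in the style of a diagnostic-statistics report."""
        c = self.counts

        def pct(e: IntervalEstimate) -> str:
            ci = f"{100 * e.lower:.2f}-{100 * e.upper:.2f}%"
            return f"{100 * e.point:.2f}%  ({ci})"

        def ratio(e: IntervalEstimate) -> str:
            hi = "inf" if math.isinf(e.upper) else f"{e.upper:.2f}"
            pt = "inf" if math.isinf(e.point) else f"{e.point:.2f}"
            return f"{pt}  ({e.lower:.2f}-{hi})"

        lines = [
            f"{'Category':<14}{'Difficult':>12}{'Easy':>10}",
            f"{'score >= cut':<14}{c.tp:>12}{c.fp:>10}",
            f"{'score <  cut':<14}{c.fn:>12}{c.tn:>10}",
            "",
            f"{'Statistic':<14}{'Value (95% CI)'}",
            f"{'Sensitivity':<14}{pct(self.sensitivity)}",
            f"{'Specificity':<14}{pct(self.specificity)}",
            f"{'PLR':<14}{ratio(self.plr)}",
            f"{'NLR':<14}{ratio(self.nlr)}",
            f"{'Prevalence':<14}{100 * self.prevalence:.2f}%",
            f"{'PPV':<14}{pct(self.ppv)}",
            f"{'NPV':<14}{pct(self.npv)}",
            f"{'Accuracy':<14}{pct(self.accuracy)}",
        ]
        return "\n".join(lines)


def build_two_by_two(
    scores: Sequence[int], labels: Sequence[bool], cutoff: int
) -> ConfusionCounts:
    """Tally the 2x2 table at a cutoff (positive: score >= cutoff)."""
    if len(scores) != len(labels):
        raise DiagnosticsError(
            f"scores ({len(scores)}) and labels ({len(labels)}) differ in length"
        )
    if len(scores) == 0:
        raise DiagnosticsError("empty input")
    if all(labels) or not any(labels):
        raise DiagnosticsError(
            "labels contain a single class; diagnostic statistics undefined"
        )
    tp = fp = fn = tn = 0
    for s, y in zip(scores, labels):
        if s >= cutoff:
            if y:
                tp += 1
            else:
                fp += 1
        else:
            if y:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Exact (Clopper-Pearson) binomial CI for a proportion k/n."""
    if not 0 <= k <= n or n == 0:
        raise DiagnosticsError(f"invalid binomial counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return IntervalEstimate(k / n, float(lo), float(hi), "clopper-pearson", level)


def _log_method_ci(
    point: float, var_log: float, level: float
) -> tuple[float, float]:
    z = _Z(0.5 + level / 2)
    half = z * math.sqrt(var_log)
    return point * math.exp(-half), point * math.exp(half)


def diagnostic_report(
    counts: ConfusionCounts,
    prevalence: Optional[float] = None,
    level: float = 0.95,
) -> DiagnosticReport:
    """Compute all diagnostic statistics at a given prevalence.

    ``prevalence`` defaults to the sample's own; supplying another value
    produces prevalence-adjusted PPV/NPV/accuracy via Bayes' theorem.
    """
    if counts.n_positive == 0 or counts.n_negative == 0:
        raise DiagnosticsError("both outcome classes must be present")
    if prevalence is None:
        prevalence = counts.sample_prevalence
    if not 0.0 < prevalence < 1.0:
        raise DiagnosticsError(f"prevalence {prevalence} outside (0, 1)")
    if not 0.0 < level < 1.0:
        raise DiagnosticsError(f"confidence level {level} outside (0, 1)")

    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n1, n0 = counts.n_positive, counts.n_negative
    p = prevalence
    z = _Z(0.5 + level / 2)

    sens = tp / n1
    spec = tn / n0
    sens_ci = clopper_pearson(tp, n1, level)
    spec_ci = clopper_pearson(tn, n0, level)

    # Likelihood ratios, log method.
    if spec < 1.0:
        plr_pt = sens / (1.0 - spec)
        if tp > 0:
            var = 1 / tp - 1 / n1 + 1 / fp - 1 / n0
            lo, hi = _log_method_ci(plr_pt, var, level)
            plr = IntervalEstimate(plr_pt, lo, hi, "log (Simel)", level)
        else:
            plr = IntervalEstimate(0.0, 0.0, 0.0, "log (Simel)", level, unbounded=True)
    else:
        plr = IntervalEstimate(
            math.inf, math.nan, math.inf, "log (Simel)", level, unbounded=True
        )
    if spec > 0.0:
        nlr_pt = (1.0 - sens) / spec
        if fn > 0:
            var = 1 / fn - 1 / n1 + 1 / tn - 1 / n0
            lo, hi = _log_method_ci(nlr_pt, var, level)
            nlr = IntervalEstimate(nlr_pt, lo, hi, "log (Simel)", level)
        else:
            nlr = IntervalEstimate(0.0, 0.0, 0.0, "log (Simel)", level, unbounded=True)
    else:
        nlr = IntervalEstimate(
            math.inf, math.nan, math.inf, "log (Simel)", level, unbounded=True
        )

    # Prevalence-adjusted predictive values, logit method.  A test that is
    # never positive (or never negative) leaves the corresponding value
    # undefined (0/0); report NaN with a flag.
    ppv_den = sens * p + (1.0 - spec) * (1.0 - p)
    ppv_pt = sens * p / ppv_den if ppv_den > 0 else math.nan
    npv_den = spec * (1.0 - p) + (1.0 - sens) * p
    npv_pt = spec * (1.0 - p) / npv_den if npv_den > 0 else math.nan
    ppv = _logit_pv_ci(ppv_pt, tp, fp, n1, n0, z, level, "ppv")
    npv = _logit_pv_ci(npv_pt, tn, fn, n0, n1, z, level, "npv")

    # Accuracy at the stated prevalence, delta method.
    acc_pt = p * sens + (1.0 - p) * spec
    var_acc = (
        p * p * sens * (1.0 - sens) / n1
        + (1.0 - p) * (1.0 - p) * spec * (1.0 - spec) / n0
    )
    half = z * math.sqrt(var_acc)
    acc = IntervalEstimate(
        acc_pt,
        max(0.0, acc_pt - half),
        min(1.0, acc_pt + half),
        "delta method",
        level,
    )

    return DiagnosticReport(
        counts=counts,
        prevalence=p,
        level=level,
        sensitivity=sens_ci,
        specificity=spec_ci,
        plr=plr,
        nlr=nlr,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
    )


def _logit_pv_ci(
    point: float,
    a: int,
    b: int,
    na: int,
    nb: int,
    z: float,
    level: float,
    which: str,
) -> IntervalEstimate:
    """Logit-method CI for a prevalence-adjusted predictive value.

    For the PPV, ``a``/``na`` are tp over the diseased and ``b``/``nb`` fp
    over the non-diseased; logit(PPV) = logit(p) + log(sens/(1-spec)), whose
    variance is (1-sens)/(sens*n1) + spec/((1-spec)*n0) — equivalently
    1/a - 1/na + 1/b - 1/nb.  Symmetric for the NPV.  Degenerate at
    point 0 or 1 (zero cell), where the interval collapses with a flag.
    """
    method = "logit (Mercaldo)"
    if math.isnan(point) or point <= 0.0 or point >= 1.0 or a == 0 or b == 0:
        return IntervalEstimate(point, point, point, method, level, unbounded=True)
    var = 1 / a - 1 / na + 1 / b - 1 / nb
    logit = math.log(point / (1.0 - point))
    half = z * math.sqrt(var)
    lo = 1.0 / (1.0 + math.exp(-(logit - half)))
    hi = 1.0 / (1.0 + math.exp(-(logit + half)))
    return IntervalEstimate(point, lo, hi, method, level)
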