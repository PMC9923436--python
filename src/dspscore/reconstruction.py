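"""Rebuilding the index cohort's grouped score distribution from summaries.

The 300-procedure index cohort on which the DSP Score was evaluated was
never deposited, but its per-group score distribution is identifiable (up
to one bin's internal split) from the published per-cutoff operating
points: with group sizes 54 difficult / 246 easy and sensitivity/
specificity printed to 3 decimals at cutoffs 2, 3 and 4, the implied bin
counts over (<2, =2, =3, >=4) round uniquely to

    difficult: 1, 27, 24, 2        easy: 139, 99, 8, 0

Re-deriving the operating points from these counts reproduces every
printed value, which is the built-in consistency check.  Only the internal
composition of the "<2" bin (score 0 vs 1) is unidentifiable; expansion to
an individual-level cohort places it at score 1 by default, a choice that
moves the AUC only in the third decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .cohort_io import Cohort, PatientRecord, ProcedureOutcome
from .roc_analysis import OperatingPoint

__all__ = [
    "GroupedScoreDistribution",
    "ReconstructionError",
    "reconstruct_from_operating_points",
    "expand_to_cohort",
    "index_operating_points",
    "index_distribution",
    "index_cohort",
    "INDEX_N_DIFFICULT",
    "INDEX_N_EASY",
]


class ReconstructionError(ValueError):
    """Raised when printed operating points are internally inconsistent."""


#: Index-cohort group sizes.
INDEX_N_DIFFICULT = 54
INDEX_N_EASY = 246


def index_operating_points() -> list[OperatingPoint]:
    """The index cohort's published per-cutoff operating points."""
    return [
        OperatingPoint(cutoff=2, sensitivity=0.981, specificity=0.565),
        OperatingPoint(cutoff=3, sensitivity=0.481, specificity=0.967),
        OperatingPoint(cutoff=4, sensitivity=0.037, specificity=1.0),
    ]


@dataclass(frozen=True)
class GroupedScoreDistribution:
    """Per-group counts over score bins, ordered low to high.

    ``bin_labels`` are ``"<c"`` for the open low bin, ``"=s"`` for single
    scores, and ``">=c"`` for the open high bin.
    """

    bin_labels: tuple[str, ...]
    difficult_counts: tuple[int, ...]
    easy_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_labels", tuple(self.bin_labels))
        object.__setattr__(self, "difficult_counts", tuple(self.difficult_counts))
        object.__setattr__(self, "easy_counts", tuple(self.easy_counts))
        if not (
            len(self.bin_labels)
            == len(self.difficult_counts)
            == len(self.easy_counts)
        ):
            raise ReconstructionError("bin labels and counts differ in length")
        if any(c < 0 for c in self.difficult_counts + self.easy_counts):
            raise ReconstructionError("negative bin count")

    @property
    def n_difficult(self) -> int:
        return sum(self.difficult_counts)

    @property
    def n_easy(self) -> int:
        return sum(self.easy_counts)

    def operating_points(self) -> list[OperatingPoint]:
        """Re-derive sens/spec at each interior cutoff from the bin counts."""
        points = []
        for i in range(1, len(self.bin_labels)):
            label = self.bin_labels[i]
            cutoff = int(label.lstrip("=>"))
            tp = sum(self.difficult_counts[i:])
            tn = sum(self.easy_counts[:i])
            points.append(
                OperatingPoint(
                    cutoff=cutoff,
                    sensitivity=tp / self.n_difficult,
                    specificity=tn / self.n_easy,
                )
            )
        return points

    def to_dict(self) -> dict:
        return {
            "bin_labels": list(self.bin_labels),
            "difficult_counts": list(self.difficult_counts),
            "easy_counts": list(self.easy_counts),
        }


def _implied_counts(n: int, fractions: Sequence[float], what: str) -> list[int]:
    """Round n*fraction at each cutoff and difference into bin counts.

    ``fractions`` are the tail probabilities (score >= cutoff) at
    consecutive cutoffs, highest fraction first; an implicit 1.0 is
    prepended and 0.0 appended.
    """
    tails = [1.0] + list(fractions) + [0.0]
    counts_ge = [int(round(n * f)) for f in tails]
    bins = [a - b for a, b in zip(counts_ge, counts_ge[1:])]
    for frac, c in zip(tails, counts_ge):
        if abs(round(c / n, 3) - round(frac, 3)) > 5e-4:
            raise ReconstructionError(
                f"{what}: implied count {c}/{n} does not reproduce the "
                f"printed fraction {frac:.3f}"
            )
    return bins


def reconstruct_from_operating_points(
    n_difficult: int,
    n_easy: int,
    points: Sequence[OperatingPoint],
) -> GroupedScoreDistribution:
    """Recover per-group bin counts from printed operating points.

    ``points`` must sit at consecutive integer cutoffs with sensitivity
    non-increasing and specificity non-decreasing.  Each group's count at
    or above a cutoff is the rounded ``n * sens`` (resp. below:
    ``n * spec``); differencing gives the bins.  The reconstruction is
    rejected if a bin count comes out negative or if the implied counts
    fail to reproduce every printed 3-decimal value.
    """
    pts = sorted(points, key=lambda p: p.cutoff)
    if not pts:
        raise ReconstructionError("no operating points supplied")
    cutoffs = [p.cutoff for p in pts]
    if cutoffs != list(range(cutoffs[0], cutoffs[0] + len(cutoffs))):
        raise ReconstructionError(f"cutoffs {cutoffs} are not consecutive integers")
    sens = [p.sensitivity for p in pts]
    spec = [p.specificity for p in pts]
    if any(a < b - 1e-9 for a, b in zip(sens, sens[1:])):
        raise ReconstructionError("sensitivity must be non-increasing in cutoff")
    if any(a > b + 1e-9 for a, b in zip(spec, spec[1:])):
        raise ReconstructionError("specificity must be non-decreasing in cutoff")

    difficult = _implied_counts(n_difficult, sens, "difficult group")
    # Specificity is the fraction *below* each cutoff: convert to tails.
    easy = _implied_counts(n_easy, [1.0 - s for s in spec], "easy group")
    for bins, grp in ((difficult, "difficult"), (easy, "easy")):
        for c, b in zip([None] + cutoffs, bins):
            if b < 0:
                raise ReconstructionError(
                    f"{grp} group: negative implied count at cutoff {c}"
                )

    labels = (
        [f"<{cutoffs[0]}"]
        + [f"={c}" for c in cutoffs[:-1]]
        + [f">={cutoffs[-1]}"]
    )
    return GroupedScoreDistribution(tuple(labels), tuple(difficult), tuple(easy))


def index_distribution() -> GroupedScoreDistribution:
    """The index cohort's grouped score distribution, reconstructed."""
    return reconstruct_from_operating_points(
        INDEX_N_DIFFICULT, INDEX_N_EASY, index_operating_points()
    )


# ---------------------------------------------------------------------------
# Expansion to an individual-level cohort
# ---------------------------------------------------------------------------

def _default_bin_rule(label: str) -> int:
    """Default representative score per bin: open bins collapse inward."""
    if label.startswith("<"):
        return int(label[1:]) - 1
    if label.startswith(">="):
        return int(label[2:])
    return int(label.lstrip("="))


#: Deterministic predictor combinations realizing each DSP score 0-7.
#: (spine_grade, experience, positioning_difficulty); grade contributes
#: grade-1 points, junior experience 1, positioning difficulty 3.
_SCORE_COMBOS: dict[int, tuple[int, str, bool]] = {
    0: (1, ">12mo", False),
    1: (2, ">12mo", False),
    2: (3, ">12mo", False),
    3: (3, "<=12mo", False),
    4: (4, "<=12mo", False),
    5: (2, "<=12mo", True),
    6: (3, "<=12mo", True),
    7: (4, "<=12mo", True),
}

#: Outcomes satisfying / failing the difficulty definition, deterministic.
_DIFFICULT_OUTCOME = ProcedureOutcome(punctures=4, passes=5)
_EASY_OUTCOME = ProcedureOutcome(punctures=1, passes=2)


def expand_to_cohort(
    dist: GroupedScoreDistribution,
    within_bin_rule: Callable[[str], int] | None = None,
    label: str = "reconstructed",
) -> Cohort:
    """Materialize a grouped distribution as an individual-level cohort.

    Each bin is assigned a concrete score by ``within_bin_rule`` (default:
    ``"<2"`` → 1, ``"=s"`` → s, ``">=4"`` → 4) and each record receives a
    deterministic predictor combination realizing that score under the DSP
    model, plus an outcome consistent with its group.  The rule is rejected
    if it assigns a score outside its bin.
    """
    rule = within_bin_rule or _default_bin_rule
    records: list[PatientRecord] = []
    idx = 0
    for label_, n_diff, n_easy in zip(
        dist.bin_labels, dist.difficult_counts, dist.easy_counts
    ):
        score = rule(label_)
        _check_score_in_bin(score, label_)
        if score not in _SCORE_COMBOS:
            raise ReconstructionError(
                f"bin {label_}: no predictor combination for score {score}"
            )
        grade, exp, pos = _SCORE_COMBOS[score]
        for is_difficult, n in ((True, n_diff), (False, n_easy)):
            outcome = _DIFFICULT_OUTCOME if is_difficult else _EASY_OUTCOME
            for _ in range(n):
                idx += 1
                records.append(
                    PatientRecord(
                        id=f"R{idx:04d}",
                        spine_grade=grade,
                        experience=exp,
                        positioning_difficulty=pos,
                        outcome=outcome,
                    )
                )
    return Cohort(records, label)


def _check_score_in_bin(score: int, label: str) -> None:
    if label.startswith("<"):
        ok = score < int(label[1:])
    elif label.startswith(">="):
        ok = score >= int(label[2:])
    else:
        ok = score == int(label.lstrip("="))
    if not ok:
        raise ReconstructionError(
            f"within-bin rule assigned score {score} outside bin {label!r}"
        )


def index_cohort() -> Cohort:
    """The reconstructed index cohort (300 records, 54 difficult)."""
    return expand_to_cohort(index_distribution(), label="index-reconstruction")
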