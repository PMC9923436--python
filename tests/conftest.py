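"""Shared fixtures: the reconstructed index cohort and small helpers."""

from __future__ import annotations

import pytest

import dspscore as d


@pytest.fixture(scope="session")
def index_cohort():
    """The 300-record cohort rebuilt from the published summary tables."""
    return d.index_cohort()


@pytest.fixture(scope="session")
def index_scores_labels(index_cohort):
    scores = [d.compute_dsp_score(r) for r in index_cohort]
    labels = [bool(r.difficult) for r in index_cohort]
    return scores, labels


@pytest.fixture(scope="session")
def index_curve(index_scores_labels):
    scores, labels = index_scores_labels
    return d.roc_from_scores(scores, labels)


def tied_rank_auc(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC with half credit for ties.

    Enumerates every (difficult, easy) pair; independent of the trapezoid
    implementation it cross-checks.
    """
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
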