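"""2x2 statistics: published-table values, CI methods, exact identities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from dspscore.diagnostics import (
    ConfusionCounts,
    DiagnosticsError,
    build_two_by_two,
    clopper_pearson,
    diagnostic_report,
)

INDEX_COUNTS = ConfusionCounts(tp=53, fp=107, fn=1, tn=139)

counts_strategy = st.tuples(
    st.integers(0, 60), st.integers(0, 200), st.integers(0, 60), st.integers(0, 200)
).filter(lambda c: c[0] + c[2] > 0 and c[1] + c[3] > 0)


class TestBuildTwoByTwo:
    def test_index_cohort_at_cutoff_2(self, index_scores_labels):
        scores, labels = index_scores_labels
        assert build_two_by_two(scores, labels, 2) == INDEX_COUNTS

    def test_cutoff_zero_makes_everyone_positive(self, index_scores_labels):
        scores, labels = index_scores_labels
        c = build_two_by_two(scores, labels, 0)
        assert c.fn == c.tn == 0
        assert c.tp == 54 and c.fp == 246

    def test_perfect_separation(self):
        assert build_two_by_two([0, 7], [False, True], 4) == ConfusionCounts(1, 0, 0, 1)

    def test_single_class_rejected(self):
        with pytest.raises(DiagnosticsError, match="single class"):
            build_two_by_two([1, 2], [True, True], 1)


@pytest.fixture(scope="module")
def report():
    return diagnostic_report(INDEX_COUNTS, prevalence=0.18)


class TestPublishedStatistics:
    """Point estimates at the published cutoff, 18% prevalence."""

    @pytest.mark.parametrize(
        "stat,expected_pct",
        [
            ("sensitivity", 98.15),
            ("specificity", 56.50),
            ("ppv", 33.12),
            ("npv", 99.29),
            ("accuracy", 64.00),
        ],
    )
    def test_percent_statistics(self, report, stat, expected_pct):
        value = 100.0 * getattr(report, stat).point
        assert value == pytest.approx(expected_pct, abs=0.0051)

    @pytest.mark.parametrize("stat,expected", [("plr", 2.26), ("nlr", 0.03)])
    def test_likelihood_ratios(self, report, stat, expected):
        assert getattr(report, stat).point == pytest.approx(expected, abs=0.005)

    def test_sensitivity_ci_clopper_pearson(self, report):
        assert 100.0 * report.sensitivity.lower == pytest.approx(90.11, abs=0.005)
        assert 100.0 * report.sensitivity.upper == pytest.approx(99.95, abs=0.005)

    def test_specificity_ci_clopper_pearson(self, report):
        assert 100.0 * report.specificity.lower == pytest.approx(50.06, abs=0.005)
        assert 100.0 * report.specificity.upper == pytest.approx(62.79, abs=0.005)

    def test_plr_ci_log_method(self, report):
        assert report.plr.lower == pytest.approx(1.95, abs=0.005)
        assert report.plr.upper == pytest.approx(2.61, abs=0.005)

    def test_nlr_ci_log_method(self, report):
        assert report.nlr.lower == pytest.approx(0.00, abs=0.005)
        assert report.nlr.upper == pytest.approx(0.23, abs=0.005)

    def test_predictive_value_cis_logit_method(self, report):
        assert 100.0 * report.ppv.lower == pytest.approx(29.95, abs=0.005)
        assert 100.0 * report.ppv.upper == pytest.approx(36.46, abs=0.005)
        assert 100.0 * report.npv.lower == pytest.approx(95.21, abs=0.005)
        assert 100.0 * report.npv.upper == pytest.approx(99.90, abs=0.005)

    def test_plr_ci_matches_closed_form(self, report):
        """Independent recomputation of the log-method interval."""
        var = 1 / 53 - 1 / 54 + 1 / 107 - 1 / 246
        z = 1.959963985
        plr = (53 / 54) / (107 / 246)
        assert report.plr.lower == pytest.approx(plr * math.exp(-z * math.sqrt(var)), rel=1e-6)
        assert report.plr.upper == pytest.approx(plr * math.exp(z * math.sqrt(var)), rel=1e-6)


class TestIdentitiesAndProperties:
    @given(c=counts_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_prevalence_consistency(self, c):
        """At the sample's own prevalence the Bayes-adjusted values reduce
        to the raw 2x2 ratios exactly."""
        counts = ConfusionCounts(*c)
        rep = diagnostic_report(counts)  # defaults to sample prevalence
        if counts.tp + counts.fp > 0:
            assert rep.ppv.point == pytest.approx(
                counts.tp / (counts.tp + counts.fp), abs=1e-12
            )
        if counts.tn + counts.fn > 0:
            assert rep.npv.point == pytest.approx(
                counts.tn / (counts.tn + counts.fn), abs=1e-12
            )
        assert rep.accuracy.point == pytest.approx(
            (counts.tp + counts.tn) / counts.total, abs=1e-12
        )

    @given(c=counts_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_plr_nlr_sign_relationship(self, c):
        """sens + spec - 1 > 0 iff PLR > 1 iff NLR < 1."""
        counts = ConfusionCounts(*c)
        rep = diagnostic_report(counts, prevalence=0.18)
        j = rep.sensitivity.point + rep.specificity.point - 1.0
        if j > 1e-12:
            assert rep.plr.point > 1.0
            assert rep.nlr.point < 1.0
        elif j < -1e-12:
            assert rep.plr.point < 1.0
            assert rep.nlr.point > 1.0

    @given(tp=st.integers(1, 50), extra=st.integers(1, 50))
    @settings(derandomize=True, max_examples=50)
    def test_sensitivity_monotone_in_tp(self, tp, extra):
        base = diagnostic_report(ConfusionCounts(tp, 5, 10, 20), 0.18)
        more = diagnostic_report(ConfusionCounts(tp + extra, 5, 10, 20), 0.18)
        assert more.sensitivity.point >= base.sensitivity.point

    def test_perfect_test_edge_cases(self):
        rep = diagnostic_report(ConfusionCounts(10, 0, 0, 10), prevalence=0.5)
        assert rep.sensitivity.point == 1.0
        assert rep.specificity.point == 1.0
        assert rep.accuracy.point == 1.0
        assert rep.nlr.point == 0.0 and rep.nlr.unbounded
        assert math.isinf(rep.plr.point) and rep.plr.unbounded

    def test_accuracy_is_prevalence_weighted_average(self):
        rep = diagnostic_report(INDEX_COUNTS, prevalence=0.3)
        expected = 0.3 * rep.sensitivity.point + 0.7 * rep.specificity.point
        assert rep.accuracy.point == pytest.approx(expected, abs=1e-12)


class TestClopperPearson:
    def test_matches_beta_quantiles(self):
        """Direct check against the defining beta quantiles."""
        iv = clopper_pearson(53, 54)
        assert iv.lower == pytest.approx(beta_dist.ppf(0.025, 53, 2), rel=1e-9)
        assert iv.upper == pytest.approx(beta_dist.ppf(0.975, 54, 1), rel=1e-9)

    @given(k=st.integers(0, 54))
    @settings(derandomize=True, max_examples=56)
    def test_contains_point_estimate(self, k):
        iv = clopper_pearson(k, 54)
        assert iv.lower <= k / 54 <= iv.upper

    def test_coverage_at_n_54(self):
        """Exact CP coverage is >= the nominal level for every p (seeded
        Monte-Carlo at the index cohort's difficult-group size)."""
        rng = np.random.default_rng(20230114)
        n = 54
        for p in (0.1, 0.5, 0.9, 0.98):
            draws = rng.binomial(n, p, size=2000)
            covered = 0
            for k in np.unique(draws):
                iv = clopper_pearson(int(k), n)
                if iv.lower <= p <= iv.upper:
                    covered += int((draws == k).sum())
            assert covered / 2000 >= 0.95

    def test_json_and_text_rendering(self):
        rep = diagnostic_report(INDEX_COUNTS, prevalence=0.18)
        text = rep.to_text()
        assert "98.15%" in text and "2.26" in text
        doc = rep.to_dict()
        assert doc["counts"] == {"tp": 53, "fp": 107, "fn": 1, "tn": 139}
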