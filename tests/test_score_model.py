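"""Score builder: weight table construction, scoring, and invariants."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dspscore.score_model import (
    CoefficientEntry,
    ScoreModel,
    ScoreModelError,
    ScorePredictor,
    build_score_from_coefficients,
    compute_dsp_score,
    dsp_coefficients,
    dsp_model,
)

GRADES = ("1", "2", "3", "4")
EXPERIENCE = ("<=12mo", ">12mo")
POSITIONING = ("absent", "present")


class TestBuilder:
    def test_published_coefficients_reproduce_weight_table(self):
        """The three printed (estimate, Pr) rows yield the published weights."""
        model = build_score_from_coefficients(dsp_coefficients(), 0.01)
        assert model.predictor("spine_grade").level_weights == {
            "1": 0, "2": 1, "3": 2, "4": 3,
        }
        assert model.predictor("positioning_difficulty").level_weights == {
            "absent": 0, "present": 3,
        }
        assert model.predictor("experience").level_weights == {
            "<=12mo": 1, ">12mo": 0,
        }
        assert model.min_score == 0
        assert model.max_score == 7

    def test_nonsignificant_entry_excluded(self):
        entries = dsp_coefficients() + [
            CoefficientEntry("bmi_high", 0.8, 0.5, "binary", ("no", "yes"))
        ]
        model = build_score_from_coefficients(entries, 0.01)
        assert {p.name for p in model.predictors} == {
            "spine_grade", "positioning_difficulty", "experience",
        }

    def test_no_significant_predictors_rejected(self):
        entries = [CoefficientEntry("x", 2.0, 0.2, "binary", ("a", "b"))]
        with pytest.raises(ScoreModelError, match="no predictor significant"):
            build_score_from_coefficients(entries, 0.01)

    def test_weight_rounding_to_zero_rejected(self):
        entries = [CoefficientEntry("x", 0.3, 0.001, "binary", ("a", "b"))]
        with pytest.raises(ScoreModelError, match="weight of 0"):
            build_score_from_coefficients(entries, 0.01)

    def test_ordinal_weight_level_mismatch_rejected(self):
        # |estimate| rounds to 2 but the predictor has 4 levels: the linear
        # 0..max assignment over levels is ambiguous and must be refused.
        entries = [CoefficientEntry("x", -2.2, 0.001, "ordinal", GRADES)]
        with pytest.raises(ScoreModelError, match="ambiguous"):
            build_score_from_coefficients(entries, 0.01)

    def test_positive_ordinal_estimate_descends_with_level(self):
        entries = [CoefficientEntry("x", 2.715, 0.001, "ordinal", GRADES)]
        model = build_score_from_coefficients(entries, 0.01)
        assert model.predictor("x").level_weights == {"1": 3, "2": 2, "3": 1, "4": 0}

    def test_binary_max_weight_level_override(self):
        entries = [CoefficientEntry("x", 1.045, 0.001, "binary", ("a", "b"))]
        default = build_score_from_coefficients(entries, 0.01)
        assert default.predictor("x").level_weights == {"a": 1, "b": 0}
        flipped = build_score_from_coefficients(
            entries, 0.01, max_weight_levels={"x": "b"}
        )
        assert flipped.predictor("x").level_weights == {"a": 0, "b": 1}

    @pytest.mark.parametrize(
        "estimate,expected_max", [(-2.715, 3), (-2.98, 3), (1.045, 1), (-2.5, 3), (1.5, 2)]
    )
    def test_half_away_from_zero_rounding(self, estimate, expected_max):
        kind = "binary" if expected_max else "binary"
        n_levels = ("a", "b")
        entries = [CoefficientEntry("x", estimate, 0.001, "binary", n_levels)]
        model = build_score_from_coefficients(entries, 0.01)
        assert model.predictor("x").max_weight == expected_max


class TestScoring:
    @pytest.mark.parametrize(
        "grade,exp,pos,expected",
        [
            ("4", "<=12mo", "present", 7),   # worst case: published maximum
            ("1", ">12mo", "absent", 0),     # best case: published minimum
            ("3", "<=12mo", "absent", 3),    # 2 + 1 + 0
        ],
    )
    def test_known_scores(self, grade, exp, pos, expected):
        levels = {
            "spine_grade": grade,
            "experience": exp,
            "positioning_difficulty": pos,
        }
        assert compute_dsp_score(levels) == expected

    def test_exhaustive_combinations_cover_full_range(self):
        """All 16 predictor combinations yield scores {0..7} with no gaps."""
        model = dsp_model()
        scores = {
            compute_dsp_score(
                {"spine_grade": g, "experience": e, "positioning_difficulty": p},
                model,
            )
            for g, e, p in itertools.product(GRADES, EXPERIENCE, POSITIONING)
        }
        assert scores == set(range(8))

    def test_monotone_in_grade_and_positioning(self):
        """Score never decreases as grade rises or positioning worsens."""
        model = dsp_model()
        for e, p in itertools.product(EXPERIENCE, POSITIONING):
            seq = [
                compute_dsp_score(
                    {"spine_grade": g, "experience": e, "positioning_difficulty": p},
                    model,
                )
                for g in GRADES
            ]
            assert seq == sorted(seq)
        for g, e in itertools.product(GRADES, EXPERIENCE):
            lo, hi = (
                compute_dsp_score(
                    {"spine_grade": g, "experience": e, "positioning_difficulty": p},
                    model,
                )
                for p in POSITIONING
            )
            assert lo <= hi

    def test_missing_and_invalid_levels_named(self):
        with pytest.raises(ScoreModelError, match="spine_grade"):
            compute_dsp_score(
                {"experience": ">12mo", "positioning_difficulty": "absent"}
            )
        with pytest.raises(ScoreModelError, match="spine_grade.*'5'"):
            compute_dsp_score(
                {
                    "spine_grade": "5",
                    "experience": ">12mo",
                    "positioning_difficulty": "absent",
                }
            )


class TestModelContainers:
    def test_json_round_trip(self):
        model = dsp_model()
        restored = ScoreModel.from_json(model.to_json())
        assert restored == model

    def test_non_monotone_weights_rejected(self):
        with pytest.raises(ScoreModelError, match="monotone"):
            ScorePredictor("x", {"a": 0, "b": 2, "c": 1}, -1.0, "increasing_with_level")

    def test_minimum_weight_must_be_zero(self):
        with pytest.raises(ScoreModelError, match="minimum"):
            ScorePredictor("x", {"a": 1, "b": 2}, -1.0, "increasing_with_level")

    @given(p=st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=25)
    def test_threshold_filter_is_strict(self, p):
        """Retention is exactly p_value < threshold for any p in [0,1]."""
        entries = dsp_coefficients() + [
            CoefficientEntry("extra", -1.0, p, "binary", ("a", "b"))
        ]
        model = build_score_from_coefficients(entries, 0.01)
        assert ("extra" in {q.name for q in model.predictors}) == (p < 0.01)
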