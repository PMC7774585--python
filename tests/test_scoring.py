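import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polyrisk import (
    ExposureProfile,
    MissingItemError,
    RawResponses,
    resolve_profile,
    rr_from_score,
    score_cohort,
    score_profile,
    summarize_scores,
)

from conftest import achievable_totals, make_reference_responses

# (score, displayed RR, decimals) pairs used for reporting
RR_PAIRS = [
    (9.0, 7.94, 2),
    (18.0, 63.10, 2),
    (-3.0, 0.5, 1),
    (14.5, 28.18, 2),
    (-14.0, 0.04, 2),
    (-1.75, 0.67, 2),
    (-15.0, 0.03, 2),
    (39.5, 8912.51, 2),
    (0.0, 1.0, 2),
]


class TestResolveProfile:
    def test_male_25_35_hit(self, registry):
        raw = make_reference_responses(sex="male", age=30.0)
        profile = resolve_profile(raw, registry)
        assert profile.selections["Male & 25-35 years old"] == "Yes"

    @pytest.mark.parametrize("age,expected", [(25.0, "Yes"), (35.0, "Yes"), (24.9, "No"), (36.0, "No")])
    def test_male_age_boundaries(self, registry, age, expected):
        raw = make_reference_responses(sex="male", age=age)
        assert resolve_profile(raw, registry).selections["Male & 25-35 years old"] == expected

    def test_female_25_35_is_no(self, registry):
        raw = make_reference_responses(sex="female", age=30.0)
        assert resolve_profile(raw, registry).selections["Male & 25-35 years old"] == "No"

    @pytest.mark.parametrize(
        "paternal_age,expected",
        [(20.0, "<35"), (34.9, "<35"), (35.0, "35-45"), (45.0, "35-45"), (45.1, ">45"), (50.0, ">45")],
    )
    def test_paternal_age_bins(self, registry, paternal_age, expected):
        raw = make_reference_responses(paternal_age=paternal_age)
        assert resolve_profile(raw, registry).selections["Paternal age"] == expected

    def test_missing_cannabis_strict_names_item(self, registry):
        raw = make_reference_responses(heavy_cannabis=None)
        with pytest.raises(MissingItemError, match="heavy cannabis use"):
            resolve_profile(raw, registry)

    def test_missing_reference_policy_imputes(self, registry):
        raw = make_reference_responses(heavy_cannabis=None)
        profile = resolve_profile(raw, registry, missing_policy="reference")
        assert profile.selections["Heavy cannabis use"] == "No"
        assert any("heavy cannabis" in w for w in profile.warnings)

    def test_white_ignores_density(self, registry):
        for density in ("low", "medium", "high"):
            raw = make_reference_responses(ethnicity="white", ethnic_density=density)
            assert resolve_profile(raw, registry).selections["Ethnicity"] == "White"

    @pytest.mark.parametrize(
        "ethnicity,density,expected",
        [
            ("black_caribbean", "low", "Black Caribbean, low ethnic density"),
            ("black_caribbean", "high", "Black Caribbean, high ethnic density"),
            ("other", "medium", "Other, medium ethnic density"),
        ],
    )
    def test_ethnicity_density_combination(self, registry, ethnicity, density, expected):
        raw = make_reference_responses(ethnicity=ethnicity, ethnic_density=density)
        assert resolve_profile(raw, registry).selections["Ethnicity"] == expected

    def test_nonwhite_missing_density_is_missing_item(self, registry):
        raw = make_reference_responses(ethnicity="other", ethnic_density=None)
        with pytest.raises(MissingItemError, match="ethnic density"):
            resolve_profile(raw, registry)

    @pytest.mark.parametrize(
        "immigration,origin,expected",
        [
            ("none", "not_applicable", "Not immigrant"),
            ("first_generation", "north_africa", "1st generation, North Africa"),
            ("first_generation", "other", "1st generation, other regions"),
            ("second_generation", "north_africa", "2nd generation, North Africa"),
            ("second_generation", "other", "2nd generation, other regions"),
        ],
    )
    def test_immigration_combination(self, registry, immigration, origin, expected):
        raw = make_reference_responses(immigration=immigration, origin=origin)
        assert resolve_profile(raw, registry).selections["Immigration"] == expected

    def test_immigrant_without_origin_is_missing(self, registry):
        raw = make_reference_responses(immigration="first_generation", origin=None)
        with pytest.raises(MissingItemError, match="origin"):
            resolve_profile(raw, registry)

    def test_implausible_combination_warns_not_errors(self, registry):
        raw = make_reference_responses(
            ethnicity="black_caribbean",
            ethnic_density="low",
            immigration="first_generation",
            origin="north_africa",
        )
        profile = resolve_profile(raw, registry)
        assert any("implausible" in w for w in profile.warnings)
        # still resolvable and scoreable
        score_profile(profile, registry)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="ethnicity"):
            RawResponses(respondent_id="x", ethnicity="martian")

    def test_age_floor(self):
        with pytest.raises(ValueError, match="inclusion floor"):
            RawResponses(respondent_id="x", age=10.0)

    def test_covers_every_group(self, registry):
        profile = resolve_profile(make_reference_responses(), registry)
        assert set(profile.selections) == set(registry.group_names)


class TestScoreProfile:
    def test_all_reference_total(self, registry):
        profile = resolve_profile(make_reference_responses(), registry)
        result = score_profile(profile, registry)
        # oracle: the enumerated achievable minimum
        assert result.total == min(achievable_totals(registry)) == -16.0

    def test_all_maximum_total(self, registry):
        selections = {
            g.name: max(g.levels, key=lambda lv: lv.weight).label for g in registry
        }
        result = score_profile(ExposureProfile(selections=selections), registry)
        assert result.total == max(achievable_totals(registry)) == 54.0

    def test_cannabis_difference_is_seven(self, registry):
        base = resolve_profile(make_reference_responses(), registry)
        high = resolve_profile(make_reference_responses(heavy_cannabis=True), registry)
        delta = score_profile(high, registry).total - score_profile(base, registry).total
        assert delta == 7.0

    def test_total_equals_sum_of_contributions(self, registry):
        result = score_profile(
            resolve_profile(make_reference_responses(childhood_trauma=True), registry),
            registry,
        )
        assert result.total == sum(result.contributions.values())
        assert set(result.contributions) == set(registry.group_names)

    def test_relative_risk_matches_total(self, registry):
        result = score_profile(resolve_profile(make_reference_responses(), registry), registry)
        assert result.relative_risk == pytest.approx(10 ** (result.total / 10))

    def test_missing_group_rejected(self, registry):
        profile = resolve_profile(make_reference_responses(), registry)
        del profile.selections["Urbanicity"]
        with pytest.raises(ValueError, match="Urbanicity"):
            score_profile(profile, registry)

    def test_unknown_level_rejected(self, registry):
        profile = resolve_profile(make_reference_responses(), registry)
        profile.selections["Urbanicity"] = "Maybe"
        with pytest.raises(KeyError):
            score_profile(profile, registry)

    def test_unknown_group_rejected(self, registry):
        profile = resolve_profile(make_reference_responses(), registry)
        profile.selections["Extra group"] = "Yes"
        with pytest.raises(ValueError, match="unknown groups"):
            score_profile(profile, registry)

    def test_every_achievable_total_is_half_integer_in_bounds(self, registry):
        totals = achievable_totals(registry)
        assert all(t * 2 == round(t * 2) for t in totals)
        assert min(totals) == -16.0 and max(totals) == 54.0


class TestRrFromScore:
    @pytest.mark.parametrize("score,expected,decimals", [(s, rr, d) for s, rr, d in RR_PAIRS])
    def test_printed_pairs(self, score, expected, decimals):
        assert round(rr_from_score(score), decimals) == expected

    def test_unit_score_at_zero(self):
        assert rr_from_score(0.0) == 1.0

    @given(
        st.floats(min_value=-30, max_value=30),
        st.floats(min_value=-30, max_value=30),
    )
    def test_log_linearity(self, a, b):
        assert rr_from_score(a + b) == pytest.approx(
            rr_from_score(a) * rr_from_score(b), rel=1e-12
        )

    @given(st.floats(min_value=-50, max_value=50), st.floats(min_value=0.001, max_value=10))
    def test_strictly_increasing(self, score, delta):
        assert rr_from_score(score + delta) > rr_from_score(score)


class TestSummarizeScores:
    def test_single_respondent(self):
        s = summarize_scores([4.5])
        assert s.mean == s.median == 4.5 and s.sd == 0.0 and s.n == 1

    def test_threshold_counting(self):
        s = summarize_scores([-2.0, 0.0, 6.0, 16.0], thresholds=[5.0, 15.0])
        assert s.threshold_proportions[5.0] == 50.0
        assert s.threshold_proportions[15.0] == 25.0

    def test_strict_inequality_at_threshold(self):
        s = summarize_scores([5.0, 5.0, 6.0, 7.0], thresholds=[5.0])
        assert s.threshold_proportions[5.0] == 50.0

    def test_quartiles_sum_to_100(self):
        rng = np.random.default_rng(0)
        s = summarize_scores(rng.normal(size=101))
        assert sum(q["percent"] for q in s.quartile_ranges) == pytest.approx(100.0)

    def test_quartile_ranges_are_observed_extrema(self):
        rng = np.random.default_rng(1)
        x = np.round(rng.normal(scale=5, size=200) * 2) / 2
        s = summarize_scores(x)
        lo_of_q1 = s.quartile_ranges[0]["range"][0]
        hi_of_q4 = s.quartile_ranges[3]["range"][1]
        assert lo_of_q1 == x.min() and hi_of_q4 == x.max()
        # bins tile the sample without overlap
        for left, right in zip(s.quartile_ranges, s.quartile_ranges[1:]):
            if left["range"] and right["range"]:
                assert left["range"][1] < right["range"][0]

    @given(st.lists(st.integers(min_value=-32, max_value=108).map(lambda k: k / 2), min_size=1, max_size=60))
    def test_quartile_percentages_property(self, totals):
        s = summarize_scores(totals)
        assert sum(q["percent"] for q in s.quartile_ranges) == pytest.approx(100.0)
        assert s.threshold_proportions[5.0] >= s.threshold_proportions[15.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_scores([])


class TestScoreCohort:
    def _cohort(self):
        return [
            make_reference_responses("a"),
            make_reference_responses("b", childhood_trauma=True),
            make_reference_responses("c", heavy_cannabis=True, daily_smoker=True),
            make_reference_responses("d", sex="male", age=30.0),
        ]

    def test_results_and_summary(self, registry):
        results, summary = score_cohort(self._cohort(), registry)
        assert [r.respondent_id for r in results] == ["a", "b", "c", "d"]
        assert summary.n == 4
        assert summary.mean == pytest.approx(np.mean([r.total for r in results]))

    def test_order_invariance(self, registry):
        _, s1 = score_cohort(self._cohort(), registry)
        _, s2 = score_cohort(list(reversed(self._cohort())), registry)
        assert s1.to_dict() == s2.to_dict()

    def test_empty_cohort_rejected(self, registry):
        with pytest.raises(ValueError, match="empty"):
            score_cohort([], registry)

    def test_exclude_policy_drops_incomplete(self, registry):
        cohort = self._cohort() + [make_reference_responses("e", heavy_cannabis=None)]
        results, summary = score_cohort(cohort, registry, missing_policy="exclude")
        assert [r.respondent_id for r in results] == ["a", "b", "c", "d"]
        assert summary.n == 4

    def test_strict_policy_raises(self, registry):
        cohort = [make_reference_responses("e", heavy_cannabis=None)]
        with pytest.raises(MissingItemError):
            score_cohort(cohort, registry)
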