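"""Exact binomial intervals, prevalence series and 2x2 contrasts."""

import datetime as dt
import math

import numpy as np
import pytest

from adtrends.claims import PopulationTable, StudyCalendar
from adtrends.episodes import TreatmentEpisode
from adtrends.prevalence import (
    PrevalenceEstimate,
    class_and_drug_profile,
    clopper_pearson,
    overall_prevalence,
    round_half_up,
    two_by_two,
    weekly_prevalence,
)

from conftest import make_record

POP = PopulationTable(total={y: 94_864 for y in range(2018, 2022)})


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        """With x = 0 the upper bound is 1 - (alpha/2)^(1/n) exactly."""
        lo, hi = clopper_pearson(0, 100, 0.05)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 100), abs=1e-12)

    def test_study_cohort_interval(self):
        """1071 users of 94,864 young adults: 95% CI ~106.3-119.8 per 10k."""
        lo, hi = clopper_pearson(1071, 94_864, 0.05)
        assert 10_000 * lo == pytest.approx(106.27, abs=0.01)
        assert 10_000 * hi == pytest.approx(119.83, abs=0.01)

    def test_boundaries(self):
        assert clopper_pearson(50, 50, 0.05)[1] == 1.0
        assert clopper_pearson(0, 1, 0.05)[0] == 0.0

    @pytest.mark.parametrize("x, n", [(5, 4), (-1, 10), (0, 0)])
    def test_invalid_inputs(self, x, n):
        with pytest.raises(ValueError):
            clopper_pearson(x, n, 0.05)

    def test_interval_orders_and_contains_point(self):
        for x, n in [(1, 10), (250, 1000), (9999, 10000)]:
            lo, hi = clopper_pearson(x, n, 0.05)
            assert 0 <= lo <= x / n <= hi <= 1


class TestOverallPrevalence:
    def test_study_cohort_rate(self):
        est = overall_prevalence({f"S{i}" for i in range(1071)}, POP)
        assert round_half_up(est.rate_per_10k) == 112.9

    def test_duplicates_counted_once(self):
        est = overall_prevalence(["A", "A", "B"], POP)
        assert est.numerator == 2

    def test_zero_users(self):
        est = overall_prevalence([], POP)
        lo, hi = est.ci_per_10k
        assert est.rate_per_10k == 0.0 and lo == 0.0 and hi > 0


def flat_episodes(n_subjects: int, calendar: StudyCalendar):
    """n subjects each active over the entire index period."""
    return {
        f"S{i}": [TreatmentEpisode(f"S{i}", "N06A", calendar.index_start,
                                   calendar.index_end, 1)]
        for i in range(n_subjects)
    }


class TestWeeklyPrevalence:
    def test_constant_cohort_gives_flat_series(self, calendar):
        pop = PopulationTable(total={y: 100_000 for y in range(2018, 2022)})
        series = weekly_prevalence(flat_episodes(50, calendar), "N06A",
                                   calendar, pop)
        assert np.allclose(series.rates, 5.0)
        lo, hi = series.estimates[0].ci_per_10k
        assert (lo, hi) == pytest.approx(
            tuple(10_000 * b for b in clopper_pearson(50, 100_000, 0.05)))

    def test_episode_week_overlap(self, calendar):
        # weeks 10..14 span days 63..97; episode [63, 98) covers all five
        start = calendar.index_start + dt.timedelta(days=63)
        eps = {"S1": [TreatmentEpisode("S1", "N06A", start,
                                       start + dt.timedelta(days=35), 1)]}
        series = weekly_prevalence(eps, "N06A", calendar, POP)
        assert list(np.nonzero(series.numerators)[0] + 1) == [10, 11, 12, 13, 14]

    def test_two_episodes_same_week_count_once(self, calendar):
        d = calendar.index_start
        eps = {"S1": [
            TreatmentEpisode("S1", "N06A", d, d + dt.timedelta(days=2), 1),
            TreatmentEpisode("S1", "N06A", d + dt.timedelta(days=4),
                             d + dt.timedelta(days=6), 1),
        ]}
        series = weekly_prevalence(eps, "N06A", calendar, POP)
        assert series.numerators[0] == 1

    def test_sex_stratum_without_sex_population_flagged(self, calendar):
        eps = flat_episodes(10, calendar)
        series = weekly_prevalence(eps, "N06A", calendar, POP, "F",
                                   sex_of_subject={f"S{i}": "F" for i in range(10)})
        assert series.denominator_is_total
        assert series.numerators[0] == 10

    def test_missing_population_year_is_error(self, calendar):
        pop = PopulationTable(total={2018: 94_864})
        with pytest.raises(KeyError, match="2019"):
            weekly_prevalence(flat_episodes(1, calendar), "N06A", calendar, pop)


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Sum of hypergeometric probabilities <= that of the observed table."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def p(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)
                / math.comb(n, r1))
    p_obs = p(a)
    return sum(p(x) for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
               if p(x) <= p_obs * (1 + 1e-12))


class TestTwoByTwo:
    def test_balanced_table(self):
        res = two_by_two(10, 90, 10, 90)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high
        assert res.p_value == pytest.approx(1.0)

    def test_wald_interval_formula(self):
        res = two_by_two(20, 80, 10, 90)
        assert res.odds_ratio == pytest.approx(2.25)
        # exp(ln 2.25 +- 1.95996 * sqrt(0.1736111))
        assert res.ci_low == pytest.approx(0.99429, abs=1e-4)
        assert res.ci_high == pytest.approx(5.09155, abs=1e-4)

    def test_fisher_matches_enumeration(self):
        for table in [(3, 1, 1, 3), (20, 80, 10, 90), (2, 8, 7, 3)]:
            res = two_by_two(*table)
            assert res.p_value == pytest.approx(
                fisher_two_sided_by_enumeration(*table), abs=1e-9)
        assert two_by_two(3, 1, 1, 3).p_value == pytest.approx(0.4857, abs=2e-4)

    def test_zero_cell_gets_continuity_correction(self):
        res = two_by_two(0, 10, 5, 5)
        assert res.continuity_corrected
        assert 0 < res.odds_ratio < 1
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_invariance_under_row_and_column_swap(self):
        res = two_by_two(12, 5, 3, 20)
        swapped = two_by_two(20, 3, 5, 12)
        assert swapped.odds_ratio == pytest.approx(res.odds_ratio)
        assert swapped.p_value == pytest.approx(res.p_value)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            two_by_two(0, 0, 5, 5)


class TestProfile:
    def _cohort(self):
        rows = []
        for i in range(6):  # 6 SSRI-only users (4 F)
            rows.append(make_record(0, atc="N06AB06", subject=f"A{i}",
                                    sex="F" if i < 4 else "M"))
        for i in range(2):  # 2 users of both SSRI and other classes
            rows.append(make_record(0, atc="N06AB06", subject=f"B{i}"))
            rows.append(make_record(5, atc="N06AX16", subject=f"B{i}",
                                    units=28, strength=75.0))
        return rows

    def test_multi_class_membership(self):
        profile = class_and_drug_profile(self._cohort(), POP)
        by_key = {r.key: r for r in profile.class_rows}
        assert by_key["N06A"].n_users == 8
        assert by_key["N06AB"].n_users == 8
        assert by_key["N06AX"].n_users == 2
        assert profile.n_multi_class == 2
        assert profile.multi_class_share == pytest.approx(0.25)

    def test_single_class_cohort_has_no_multi_users(self):
        rows = [make_record(0, subject=f"S{i}") for i in range(5)]
        assert class_and_drug_profile(rows, POP).n_multi_class == 0

    def test_ssri_prevalence_chain(self):
        """783 SSRI users of 94,864 inhabitants print as 82.5 per 10,000."""
        rows = [make_record(0, subject=f"S{i}") for i in range(783)]
        profile = class_and_drug_profile(rows, POP)
        ssri = {r.key: r for r in profile.class_rows}["N06AB"]
        assert round_half_up(ssri.prevalence.rate_per_10k) == 82.5
        lo, hi = ssri.prevalence.ci_per_10k
        assert (round_half_up(lo), round_half_up(hi)) == (76.9, 88.5)

    def test_empty_class_row_present_with_zero_rate(self):
        profile = class_and_drug_profile(self._cohort(), POP)
        n06aa = {r.key: r for r in profile.class_rows}["N06AA"]
        assert n06aa.n_users == 0
        assert n06aa.prevalence.rate_per_10k == 0.0


class TestRounding:
    @pytest.mark.parametrize("x, expected", [
        (112.85, 112.9), (112.84999, 112.8), (0.05, 0.1), (24.55, 24.6),
    ])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected


def test_estimate_invariants():
    est = PrevalenceEstimate(50, 100_000)
    lo, hi = est.ci_per_10k
    assert 0 <= lo <= est.rate_per_10k <= hi <= 10_000
    with pytest.raises(ValueError):
        PrevalenceEstimate(5, 4)
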