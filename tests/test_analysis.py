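"""Cohort aggregation, pooling, CFRs, event tables and comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nearmiss import published
from nearmiss.analysis import (
    case_fatality_rate,
    compare_categorical,
    compare_numeric,
    deaths_without_organ_dysfunction,
    detection_delta,
    event_table,
    format_event_table,
    life_threatening_population,
    pooled_counts,
    pooled_detection,
    round0,
    round1,
    summarize_cohort,
)
from nearmiss.classify import classify_cohort
from nearmiss.records import Conditions, Interventions, ToolConfig, Uterine


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(90.85, 90.9), (87.249, 87.2), (2.25, 2.3), (-2.25, -2.3), (0.04, 0.0)],
    )
    def test_round1_half_away_from_zero(self, value, expected):
        assert round1(value) == expected

    @pytest.mark.parametrize("value, expected", [(35.4, 35), (32.6, 33), (0.5, 1)])
    def test_round0(self, value, expected):
        assert round0(value) == expected


def _cohort(make_record, n, n_group_c=0, n_died=0, cohort_id="X"):
    records = []
    for i in range(n):
        records.append(
            make_record(
                cohort_id=cohort_id,
                died=i < n_died,
                conditions=Conditions(severe_pph=i % 2 == 0),
                uterine=Uterine(hysterectomy_for_hemorrhage_or_infection=i < n_group_c),
            )
        )
    return classify_cohort(records)


class TestSummarize:
    def test_detection_fraction(self, make_record):
        summary = summarize_cohort(_cohort(make_record, 10, n_group_c=4))
        assert summary.group_counts["C"] == 4
        assert summary.group_percents["C"] == 40.0

    def test_everyone_dies_cfr_100(self, make_record):
        summary = summarize_cohort(_cohort(make_record, 8, n_died=8))
        assert summary.cfr_percent == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([])

    def test_mixed_cohorts_rejected(self, make_record):
        mixed = _cohort(make_record, 2, cohort_id="A") + _cohort(make_record, 2, cohort_id="B")
        with pytest.raises(ValueError, match="multiple cohorts"):
            summarize_cohort(mixed)

    def test_unassessable_records_excluded_from_denominators(self, make_record):
        results = _cohort(make_record, 4, n_group_c=2) + classify_cohort([make_record()])
        summary = summarize_cohort(results)
        assert summary.n_women == 4
        assert summary.n_excluded == 1
        assert summary.group_percents["C"] == 50.0

    def test_band_counts_sum_to_available(self, make_record):
        records = [
            make_record(age_years=a, parity=p, units_blood=u, conditions=Conditions(severe_pph=True))
            for a, p, u in [(19, 0, 0), (25, 1, 5), (40, 3, 2), (None, None, None)]
        ]
        summary = summarize_cohort(classify_cohort(records))
        for banded in (summary.age_bands, summary.parity_bands, summary.units_bands):
            assert sum(banded.counts.values()) == banded.n_available
            assert banded.n_available == 3 <= summary.n_women


class TestPooled:
    def test_disease_based_pooling(self):
        count, n, percent = pooled_counts([(2308, 2538), (123, 248), (336, 386)])
        assert (count, n, percent) == (2767, 3172, 87.2)

    def test_organ_dysfunction_pooling(self):
        count, n, percent = pooled_counts([(1024, 2538), (103, 248), (84, 386)])
        assert (count, n, percent) == (1211, 3172, 38.2)

    def test_single_cohort_identity(self, make_record):
        summary = summarize_cohort(_cohort(make_record, 10, n_group_c=4))
        count, n, percent = pooled_detection([summary], "C")
        assert (count, n, percent) == (4, 10, summary.group_percents["C"])

    def test_pooled_percent_between_extremes(self):
        _, _, percent = pooled_counts([(10, 100), (90, 100)])
        assert 10.0 <= percent <= 90.0


class TestCorrection:
    def test_published_correction_totals(self):
        un = pooled_counts([(1024, 2538), (103, 248), (84, 386)])
        co = pooled_counts([(1024, 2538), (228, 248), (206, 386)])
        assert un[0] == 1211 and co[0] == 1458
        assert co[2] == 46.0
        assert detection_delta(un[2], co[2]) == 7.8

    def test_delta_identity_and_bounds(self):
        assert detection_delta(42.0, 42.0) == 0.0
        with pytest.raises(ValueError):
            detection_delta(-1.0, 50.0)

    def test_life_threatening_subset_relations(self, make_record):
        corrected = ToolConfig(any_transfusion_low_resource=True)
        records = [
            make_record(setting="low_resource", units_blood=u, conditions=Conditions(severe_pph=True))
            for u in (0, 1, 5)
        ]
        plain = classify_cohort(records)
        fixed = classify_cohort(records, corrected)
        lt_plain, _ = life_threatening_population(plain)
        lt_fixed, _ = life_threatening_population(fixed, corrected)
        assert {id(r.record) for r in lt_plain} <= {id(r.record) for r in lt_fixed}
        # every group-C woman is in the uncorrected life-threatening set
        assert all(r.life_threatening for r in plain if r.group_c)

    def test_high_resource_unaffected_by_flag(self, make_record):
        corrected = ToolConfig(any_transfusion_low_resource=True)
        record = make_record(setting="high_resource", units_blood=2, conditions=Conditions(severe_pph=True))
        plain, fixed = classify_cohort([record]), classify_cohort([record], corrected)
        assert plain[0].life_threatening == fixed[0].life_threatening == False  # noqa: E712


class TestCFR:
    @pytest.mark.parametrize(
        "deaths, n, expected",
        [(48, 2538, 1.9), (32, 248, 12.9), (46, 386, 11.9), (13, 123, 10.6), (0, 100, 0.0)],
    )
    def test_published_cfrs(self, deaths, n, expected):
        assert case_fatality_rate(deaths, n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            case_fatality_rate(1, 0)
        with pytest.raises(ValueError):
            case_fatality_rate(5, 4)


class TestDeathsWithoutOrganDysfunction:
    def test_fraction_of_deaths(self, make_record):
        # 2 deaths without organ dysfunction out of 6 deaths -> 33%
        results = _cohort(make_record, 10, n_group_c=4, n_died=6)
        count, percent = deaths_without_organ_dysfunction(results)
        assert (count, percent) == (2, 33)

    def test_all_deaths_captured(self, make_record):
        results = _cohort(make_record, 6, n_group_c=6, n_died=3)
        assert deaths_without_organ_dysfunction(results) == (0, 0)

    def test_no_deaths(self, make_record):
        results = _cohort(make_record, 4)
        assert deaths_without_organ_dysfunction(results) == (0, None)


class TestEventTable:
    def test_hand_counted_example(self, make_record):
        records = [
            make_record(conditions=Conditions(severe_pph=True)),
            make_record(conditions=Conditions(severe_pph=True, eclampsia=True)),
            make_record(conditions=Conditions(eclampsia=True)),
        ]
        summary = summarize_cohort(classify_cohort(records))
        table = event_table([summary])
        assert table.attrs["denominators"][("A", "X")] == 4
        assert table.loc[("A", "A0"), "X"].item() == 2
        rendered = format_event_table(table)
        assert rendered.loc[("A", "A0"), "X"].item() == "2 (50.0)"

    def test_not_applicable_rendered_distinctly(self, make_record, study_config):
        records = [
            make_record(
                cohort_id="MW",
                setting="low_resource",
                units_blood=1,
                interventions=Interventions(laparotomy_non_cs=True),
            )
        ]
        summary = summarize_cohort(classify_cohort(records, study_config), study_config)
        table = event_table([summary])
        rendered = format_event_table(table)
        assert rendered.loc[("B", "B1"), "MW"].item() == "N/A"
        assert rendered.loc[("B", "B3"), "MW"].item() == "N/A"
        # B denominator excludes the unavailable criteria
        assert table.attrs["denominators"][("B", "MW")] == 2  # B0 + B2

    def test_published_nl_disease_denominator(self):
        nl_events = [published.EVENT_COUNTS[c]["NL"] for c in ("A0", "A1", "A2", "A3", "A4")]
        assert sum(nl_events) == 2638


class TestCompareCategorical:
    def test_homogeneous_table(self):
        result = compare_categorical([[10, 10], [10, 10]])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)
        assert result.flag == "ns"

    def test_matches_brute_force_oracle(self):
        observed = np.array([[50, 5], [5, 50]], dtype=float)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        stat = ((observed - expected) ** 2 / expected).sum()
        result = compare_categorical(observed.astype(int))
        assert result.statistic == pytest.approx(stat)
        assert result.flag == "b"

    def test_uterine_rupture_row_not_significant(self):
        # women with vs without a ruptured-uterus event, per cohort
        rupture = {c: published.EVENT_COUNTS["A4"][c] for c in published.COHORTS}
        table = pd.DataFrame(
            {c: [rupture[c], published.COHORT_N[c] - rupture[c]] for c in published.COHORTS},
            index=["ruptured uterus", "no rupture"],
        )
        result = compare_categorical(table)
        assert result.p_value > 0.05
        assert result.flag == "ns"

    def test_zero_marginal_names_category(self):
        table = pd.DataFrame({"a": [0, 5], "b": [0, 7]}, index=["empty", "full"])
        with pytest.raises(ValueError, match="empty"):
            compare_categorical(table)

    def test_rejects_tiny_or_negative(self):
        with pytest.raises(ValueError):
            compare_categorical([[1, 2]])
        with pytest.raises(ValueError):
            compare_categorical([[1, -2], [3, 4]])


class TestCompareNumeric:
    def test_identical_samples(self):
        result = compare_numeric([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(5.0, 1.0, size=40)
        assert compare_numeric(a, b).p_value < 0.05

    def test_matches_pooled_variance_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        na, nb = 3, 3
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert compare_numeric(a, b).statistic == pytest.approx(t)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            compare_numeric([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_numeric([2.0, 2.0], [3.0, 3.0])
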