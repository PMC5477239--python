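"""The WHO MNM rule engine: thresholds, missingness, applicability, purity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nearmiss.catalog import (
    CATALOG,
    NA,
    catalog_table,
    criterion,
    evaluate_criterion,
)
from nearmiss.classify import classify_record
from nearmiss.records import (
    Coagulation,
    Conditions,
    Interventions,
    Neurologic,
    Renal,
    ToolConfig,
    creatinine_mgdl_to_umol,
)
from who_oracle import build_record, oracle_met, random_grid_record


class TestCatalogStructure:
    def test_group_sizes(self):
        groups = [c.group for c in CATALOG]
        assert groups.count("A") == 5
        assert groups.count("B") == 4
        assert groups.count("C") == 7

    def test_ids_unique_and_ordered(self):
        ids = [c.id for c in CATALOG]
        assert len(set(ids)) == 16
        assert ids == sorted(ids)  # A0..A4, B0..B3, C0..C6

    def test_catalog_table_is_machine_readable(self):
        table = catalog_table()
        assert set(table.columns) == {"id", "group", "label", "clause"}
        assert table["id"].nunique() == 16
        # each clause of the engine appears exactly once
        assert len(table) == sum(len(c.clauses) for c in CATALOG)

    def test_unknown_criterion_raises_with_id(self, make_record):
        with pytest.raises(KeyError, match="Z9"):
            evaluate_criterion(make_record(), "Z9")


class TestThresholds:
    """Boundary behaviour follows the printed inequality directions."""

    @pytest.mark.parametrize(
        "units, expected", [(5, True), (6, True), (4, False), (0, False), (None, False)]
    )
    def test_massive_transfusion_boundary(self, make_record, units, expected):
        record = make_record(units_blood=units)
        assert evaluate_criterion(record, "C3") is expected

    @pytest.mark.parametrize("platelets, expected", [(49_000, True), (50_000, False)])
    def test_thrombocytopenia_strictly_below(self, make_record, platelets, expected):
        record = make_record(coagulation=Coagulation(platelets=platelets))
        assert evaluate_criterion(record, "C3") is expected

    def test_creatinine_mgdl_converts_then_triggers(self, make_record):
        # 3.5 mg/dl x 88.4 = 309.4 umol/l >= 300
        umol = creatinine_mgdl_to_umol(3.5)
        assert umol == pytest.approx(309.4)
        record = make_record(renal=Renal(creatinine=umol))
        assert evaluate_criterion(record, "C2") is True
        assert evaluate_criterion(make_record(renal=Renal(creatinine=299.9)), "C2") is False

    @pytest.mark.parametrize(
        "field_values, criterion_id, expected",
        [
            ({"cardiovascular": {"lactate": 5.0}}, "C0", False),
            ({"cardiovascular": {"lactate": 5.1}}, "C0", True),
            ({"cardiovascular": {"ph": 7.1}}, "C0", False),
            ({"cardiovascular": {"ph": 7.09}}, "C0", True),
            ({"respiratory": {"respiratory_rate": 40}}, "C1", False),
            ({"respiratory": {"respiratory_rate": 41}}, "C1", True),
            ({"respiratory": {"respiratory_rate": 6}}, "C1", False),
            ({"respiratory": {"respiratory_rate": 5}}, "C1", True),
            ({"respiratory": {"pao2_fio2": 199}}, "C1", True),
            ({"respiratory": {"pao2_fio2": 200}}, "C1", False),
            ({"hepatic": {"bilirubin": 100}}, "C4", False),
            ({"hepatic": {"bilirubin": 101}}, "C4", True),
        ],
    )
    def test_lab_boundaries(self, make_record, field_values, criterion_id, expected):
        record = make_record(**field_values)
        assert evaluate_criterion(record, criterion_id) is expected

    def test_lowering_threshold_config(self, make_record):
        record = make_record(units_blood=4)
        assert evaluate_criterion(record, "C3") is False
        lowered = ToolConfig(massive_transfusion_threshold=4)
        assert evaluate_criterion(record, "C3", lowered) is True


class TestApplicability:
    def test_unavailable_intervention_is_na_not_false(self, make_record):
        config = ToolConfig(available_interventions={"MW": frozenset({"laparotomy_non_cs"})})
        record = make_record(
            cohort_id="MW",
            setting="low_resource",
            interventions=Interventions(icu_admission=True),
        )
        assert evaluate_criterion(record, "B3", config) is NA
        assert evaluate_criterion(record, "B1", config) is NA
        assert evaluate_criterion(record, "B3") is True  # default config: ICU exists

    def test_availability_never_touches_groups_a_and_c(self, make_record):
        config = ToolConfig(available_interventions={"MW": frozenset()})
        record = make_record(
            cohort_id="MW",
            setting="low_resource",
            units_blood=5,
            conditions=Conditions(eclampsia=True),
        )
        result = classify_record(record, config)
        assert {"A2", "C3", "B0"} <= result.met  # B0 depends only on units_blood
        assert result.not_applicable == {"B1", "B2", "B3"}


class TestClassify:
    def test_empty_record_meets_nothing(self, make_record):
        result = classify_record(make_record())
        assert result.met == frozenset()
        assert not (result.group_a or result.group_b or result.group_c)
        assert not result.life_threatening

    def test_multi_group_record(self, make_record):
        record = make_record(
            conditions=Conditions(eclampsia=True),
            interventions=Interventions(icu_admission=True),
            neurologic=Neurologic(unconscious_ge12h=True),
        )
        result = classify_record(record)
        assert result.met == {"A2", "B3", "C5"}
        assert len(result.events) == 3
        assert result.life_threatening

    def test_one_event_per_criterion(self, make_record):
        # several positive markers within one subcategory still count once
        record = make_record(cardiovascular={"shock": True, "cpr": True, "cardiac_arrest": True})
        result = classify_record(record)
        assert result.events.count("C0") == 1
        assert set(result.events) == result.met

    def test_any_transfusion_rule_low_resource_only(self, make_record):
        corrected = ToolConfig(any_transfusion_low_resource=True)
        low = make_record(setting="low_resource", units_blood=1)
        assert classify_record(low, corrected).life_threatening
        assert not classify_record(low, corrected).group_c
        assert not classify_record(low).life_threatening  # flag off
        high = make_record(setting="high_resource", units_blood=1)
        assert not classify_record(high, corrected).life_threatening

    def test_incomplete_and_assessable_flags(self, make_record):
        blank = make_record()
        result = classify_record(blank)
        assert result.incomplete and not result.assessable
        partial = make_record(conditions=Conditions(severe_pph=False))
        result = classify_record(partial)
        assert result.incomplete and result.assessable  # B and C groups unrecorded

    def test_determinism(self, make_record):
        record = make_record(units_blood=5, conditions=Conditions(severe_pph=True))
        assert classify_record(record) == classify_record(record)


class TestOracleEquivalence:
    def test_grid_agreement_with_brute_force(self):
        """Engine equals an independently written clause evaluation on >=10^4
        random assignments from the discretized marker grid."""
        rng = np.random.default_rng(20170619)
        config = ToolConfig()
        for _ in range(10_000):
            d = random_grid_record(rng)
            record = build_record(d)
            result = classify_record(record, config)
            assert result.met == oracle_met(d)

    def test_grid_group_flags_consistent(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            d = random_grid_record(rng)
            result = classify_record(build_record(d))
            expected = oracle_met(d)
            assert result.group_c == any(i.startswith("C") for i in expected)
            assert result.life_threatening == result.group_c  # default config


_flag3 = st.sampled_from([None, False, True])
_marker_dicts = st.fixed_dictionaries(
    {
        "severe_pph": _flag3,
        "eclampsia": _flag3,
        "icu_admission": _flag3,
        "shock": _flag3,
        "failure_to_form_clots": _flag3,
        "hysterectomy": _flag3,
        "units": st.sampled_from([None, 0, 1, 3, 4, 5, 7]),
        "platelets": st.sampled_from([None, 30_000.0, 50_000.0, 80_000.0]),
        "lactate": st.sampled_from([None, 2.0, 5.0, 9.0]),
    }
)


class TestMonotonicity:
    @given(_marker_dicts)
    def test_lowering_transfusion_threshold_never_shrinks_group_c(self, d):
        record = build_record(d)
        met5 = classify_record(record, ToolConfig(massive_transfusion_threshold=5)).met
        met1 = classify_record(record, ToolConfig(massive_transfusion_threshold=1)).met
        assert met5 <= met1

    @given(_marker_dicts)
    def test_correction_flag_never_shrinks_life_threatening(self, d):
        record = build_record(d, setting="low_resource")
        plain = classify_record(record, ToolConfig())
        corrected = classify_record(record, ToolConfig(any_transfusion_low_resource=True))
        assert corrected.life_threatening >= plain.life_threatening
        assert corrected.group_c == plain.group_c

    @given(_marker_dicts, st.sampled_from(["severe_pph", "shock", "icu_admission", "hysterectomy"]))
    def test_setting_a_flag_true_never_removes_criteria(self, d, flag):
        base = classify_record(build_record(d)).met
        worse = dict(d)
        worse[flag] = True
        assert base <= classify_record(build_record(worse)).met

    @given(_marker_dicts)
    def test_pathological_lab_shift_never_removes_criteria(self, d):
        base = classify_record(build_record(d)).met
        worse = dict(d)
        if worse["platelets"] is not None:
            worse["platelets"] = 10_000.0
        if worse["lactate"] is not None:
            worse["lactate"] = 12.0
        assert base <= classify_record(build_record(worse)).met
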