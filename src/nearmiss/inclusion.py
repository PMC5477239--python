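"""Local severe-maternal-outcome (SMO) inclusion criteria of the three studies.

Each of the three cohorts — the Dutch nationwide LEMMoN study, the Tanzanian
Haydom Lutheran Hospital study and the Malawian Thyolo District "4M" study —
recruited women by its own locally feasible SMO definition before the WHO MNM
tool was applied. These rule sets matter scientifically: differences in local
inclusion (e.g. Tanzania including haemorrhage only via transfusion or a low
haemoglobin, Malawi including any transfused woman) drive part of the
between-setting differences in WHO-tool detection.

Predicates are pure and missing-safe: an unrecorded marker never includes a
woman.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .records import PatientRecord

__all__ = [
    "InclusionGroup",
    "InclusionRuleSet",
    "InclusionDecision",
    "RULESETS",
    "ruleset",
    "check_smo_inclusion",
]


def _t(v) -> bool:
    return v is True


@dataclass(frozen=True)
class InclusionGroup:
    """One named inclusion group of a local SMO definition."""

    name: str
    predicate: Callable[[PatientRecord], bool]


@dataclass(frozen=True)
class InclusionRuleSet:
    name: str
    groups: tuple[InclusionGroup, ...]


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    matched_groups: tuple[str, ...]


# --- The Netherlands: LEMMoN ---------------------------------------------

def _nl_icu(r: PatientRecord) -> bool:
    return _t(r.interventions.icu_admission)


def _nl_rupture(r: PatientRecord) -> bool:
    return _t(r.conditions.uterine_rupture)


def _nl_eclampsia_hellp(r: PatientRecord) -> bool:
    # HELLP only counted when severe; represented by the severe pre-eclampsia flag
    return _t(r.conditions.eclampsia) or _t(r.conditions.severe_preeclampsia)


def _nl_moh(r: PatientRecord) -> bool:
    # transfusion of >= 4 units of packed cells, or embolization or
    # hysterectomy for major obstetric haemorrhage
    return (
        (r.units_blood is not None and r.units_blood >= 4)
        or _t(r.interventions.interventional_radiology)
        or _t(r.uterine.hysterectomy_for_hemorrhage_or_infection)
    )


def _nl_misc(r: PatientRecord) -> bool:
    return _t(r.extras.clinician_judged_severe)


# --- Tanzania: Haydom ------------------------------------------------------

def _tz_clinical(r: PatientRecord) -> bool:
    rr = r.respiratory.respiratory_rate
    return (
        _t(r.respiratory.acute_cyanosis)
        or _t(r.respiratory.gasping)
        or (rr is not None and (rr > 40 or rr < 6))
        or _t(r.cardiovascular.shock)
        or _t(r.renal.oliguria_nonresponsive)
        or _t(r.coagulation.failure_to_form_clots)
        or _t(r.neurologic.unconscious_ge12h)
        or _t(r.cardiovascular.cardiac_arrest)
        or _t(r.neurologic.stroke)
        or _t(r.neurologic.uncontrollable_fits_status_epilepticus)
        or _t(r.neurologic.total_paralysis)
        or _t(r.hepatic.jaundice_with_preeclampsia)
    )


def _tz_laboratory(r: PatientRecord) -> bool:
    return (
        _t(r.respiratory.hypoxemia_spo2_lt90_ge60min)
        or (r.coagulation.platelets is not None and r.coagulation.platelets < 50_000)
    )


def _tz_rupture(r: PatientRecord) -> bool:
    return _t(r.conditions.uterine_rupture)


def _tz_eclampsia(r: PatientRecord) -> bool:
    return _t(r.conditions.eclampsia) or _t(r.conditions.severe_preeclampsia)


def _tz_moh(r: PatientRecord) -> bool:
    # transfusion of units (>= 450 ml, i.e. any unit), haemoglobin < 6 g/dl
    # after vaginal bleeding, or estimated blood loss > 1 l
    return (
        (r.units_blood is not None and r.units_blood >= 1)
        or (r.extras.hemoglobin is not None and r.extras.hemoglobin < 6.0)
        or (r.extras.estimated_blood_loss is not None and r.extras.estimated_blood_loss > 1000.0)
    )


def _tz_infection(r: PatientRecord) -> bool:
    return _t(r.conditions.sepsis_severe_infection) or _t(r.extras.iv_antimicrobials)


def _tz_other(r: PatientRecord) -> bool:
    return _t(r.extras.clinician_judged_severe)


# --- Malawi: 4M ------------------------------------------------------------

def _mw_management(r: PatientRecord) -> bool:
    # ICU admission, hysterectomy following infection or haemorrhage,
    # transfusion of >= 1 unit of blood, intubation/ventilation >= 60 min not
    # related to anaesthesia, cardiopulmonary resuscitation
    return (
        _t(r.interventions.icu_admission)
        or _t(r.uterine.hysterectomy_for_hemorrhage_or_infection)
        or (r.units_blood is not None and r.units_blood >= 1)
        or _t(r.respiratory.intubation_non_anesthesia)
        or _t(r.cardiovascular.cpr)
    )


def _mw_rupture(r: PatientRecord) -> bool:
    return _t(r.conditions.uterine_rupture) or _t(r.interventions.laparotomy_non_cs)


def _mw_eclampsia(r: PatientRecord) -> bool:
    return _t(r.conditions.eclampsia) or _t(r.conditions.severe_preeclampsia)


def _mw_complications(r: PatientRecord) -> bool:
    return (
        _t(r.conditions.eclampsia)
        or _t(r.conditions.sepsis_severe_infection)
        or _t(r.conditions.uterine_rupture)
        or _t(r.extras.iv_antimicrobials)
    )


NETHERLANDS_LEMMON = InclusionRuleSet(
    "netherlands_lemmon",
    (
        InclusionGroup("ICU admission", _nl_icu),
        InclusionGroup("Uterine rupture", _nl_rupture),
        InclusionGroup("Eclampsia/HELLP", _nl_eclampsia_hellp),
        InclusionGroup("Major obstetric haemorrhage", _nl_moh),
        InclusionGroup("Miscellaneous", _nl_misc),
    ),
)

TANZANIA_HAYDOM = InclusionRuleSet(
    "tanzania_haydom",
    (
        InclusionGroup("Clinical criteria", _tz_clinical),
        InclusionGroup("Laboratory-based criteria", _tz_laboratory),
        InclusionGroup("Uterine rupture", _tz_rupture),
        InclusionGroup("Eclampsia or severe pre-eclampsia", _tz_eclampsia),
        InclusionGroup("Major obstetric haemorrhage", _tz_moh),
        InclusionGroup("Severe peripartum infections", _tz_infection),
        InclusionGroup("Other severe complication", _tz_other),
    ),
)

MALAWI_4M = InclusionRuleSet(
    "malawi_4m",
    (
        InclusionGroup("Management-based criteria", _mw_management),
        InclusionGroup("Uterine rupture", _mw_rupture),
        InclusionGroup("Eclampsia or severe pre-eclampsia", _mw_eclampsia),
        InclusionGroup("Severe maternal complications", _mw_complications),
    ),
)

RULESETS: dict[str, InclusionRuleSet] = {
    rs.name: rs for rs in (NETHERLANDS_LEMMON, TANZANIA_HAYDOM, MALAWI_4M)
}


def ruleset(name: str) -> InclusionRuleSet:
    """Look up an inclusion rule set by name."""
    try:
        return RULESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown rule set {name!r}; available: {sorted(RULESETS)}"
        ) from None


def check_smo_inclusion(record: PatientRecord, rules: InclusionRuleSet) -> InclusionDecision:
    """Would this woman have been recruited as SMO by the given local study?

    Returns the decision together with the names of all inclusion groups she
    matches (a woman can match several).
    """
    matched = tuple(g.name for g in rules.groups if g.predicate(record))
    return InclusionDecision(included=bool(matched), matched_groups=matched)
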