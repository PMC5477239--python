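"""Independent brute-force oracle for the WHO MNM criteria.

Written directly from the tool's published criteria table, clause by clause,
over a flat dict of marker values — deliberately sharing no code with
``nearmiss.catalog``. Used to cross-check the rule engine on a discretized
marker grid.
"""

from __future__ import annotations

from nearmiss.records import (
    Cardiovascular,
    Coagulation,
    Conditions,
    Hepatic,
    Interventions,
    Neurologic,
    PatientRecord,
    Renal,
    Respiratory,
    Uterine,
)

FLAG_KEYS = (
    "severe_pph",
    "severe_preeclampsia",
    "eclampsia",
    "sepsis_severe_infection",
    "uterine_rupture",
    "interventional_radiology",
    "laparotomy_non_cs",
    "icu_admission",
    "shock",
    "cardiac_arrest",
    "vasoactive_drugs",
    "cpr",
    "acute_cyanosis",
    "gasping",
    "intubation_non_anesthesia",
    "hypoxemia",
    "oliguria",
    "dialysis",
    "failure_to_form_clots",
    "jaundice",
    "unconscious",
    "stroke",
    "fits",
    "paralysis",
    "hysterectomy",
)

# absent / below / at / above each printed threshold
LAB_GRID = {
    "lactate": (None, 4.0, 5.0, 5.5),
    "ph": (None, 7.0, 7.1, 7.2),
    "respiratory_rate": (None, 4.0, 6.0, 40.0, 41.0),
    "pao2_fio2": (None, 150.0, 200.0, 250.0),
    "creatinine": (None, 299.0, 300.0, 350.0),
    "platelets": (None, 49_999.0, 50_000.0, 60_000.0),
    "bilirubin": (None, 99.0, 100.0, 101.0),
    "units": (None, 0, 1, 4, 5, 6),
}


def _on(d, key):
    return d.get(key) is True


def oracle_met(d: dict) -> set[str]:
    """Criterion ids a marker assignment satisfies, per the published table."""
    met = set()
    if _on(d, "severe_pph"):
        met.add("A0")
    if _on(d, "severe_preeclampsia"):
        met.add("A1")
    if _on(d, "eclampsia"):
        met.add("A2")
    if _on(d, "sepsis_severe_infection"):
        met.add("A3")
    if _on(d, "uterine_rupture"):
        met.add("A4")
    units = d.get("units")
    if units is not None and units >= 1:
        met.add("B0")
    if _on(d, "interventional_radiology"):
        met.add("B1")
    if _on(d, "laparotomy_non_cs"):
        met.add("B2")
    if _on(d, "icu_admission"):
        met.add("B3")
    lact, ph = d.get("lactate"), d.get("ph")
    if (
        _on(d, "shock")
        or _on(d, "cardiac_arrest")
        or _on(d, "vasoactive_drugs")
        or _on(d, "cpr")
        or (lact is not None and lact > 5)
        or (ph is not None and ph < 7.1)
    ):
        met.add("C0")
    rr, pf = d.get("respiratory_rate"), d.get("pao2_fio2")
    if (
        _on(d, "acute_cyanosis")
        or _on(d, "gasping")
        or (rr is not None and (rr > 40 or rr < 6))
        or _on(d, "intubation_non_anesthesia")
        or _on(d, "hypoxemia")
        or (pf is not None and pf < 200)
    ):
        met.add("C1")
    creat = d.get("creatinine")
    if _on(d, "oliguria") or _on(d, "dialysis") or (creat is not None and creat >= 300):
        met.add("C2")
    plate = d.get("platelets")
    if (
        _on(d, "failure_to_form_clots")
        or (units is not None and units >= 5)
        or (plate is not None and plate < 50_000)
    ):
        met.add("C3")
    bili = d.get("bilirubin")
    if _on(d, "jaundice") or (bili is not None and bili > 100):
        met.add("C4")
    if _on(d, "unconscious") or _on(d, "stroke") or _on(d, "fits") or _on(d, "paralysis"):
        met.add("C5")
    if _on(d, "hysterectomy"):
        met.add("C6")
    return met


def build_record(
    d: dict, cohort_id: str = "X", setting: str = "high_resource", died: bool = False
) -> PatientRecord:
    """Materialize a flat marker dict as a validated PatientRecord."""
    return PatientRecord(
        cohort_id=cohort_id,
        setting=setting,
        died=died,
        units_blood=d.get("units"),
        conditions=Conditions(
            severe_pph=d.get("severe_pph"),
            severe_preeclampsia=d.get("severe_preeclampsia"),
            eclampsia=d.get("eclampsia"),
            sepsis_severe_infection=d.get("sepsis_severe_infection"),
            uterine_rupture=d.get("uterine_rupture"),
        ),
        interventions=Interventions(
            interventional_radiology=d.get("interventional_radiology"),
            laparotomy_non_cs=d.get("laparotomy_non_cs"),
            icu_admission=d.get("icu_admission"),
        ),
        cardiovascular=Cardiovascular(
            shock=d.get("shock"),
            cardiac_arrest=d.get("cardiac_arrest"),
            vasoactive_drugs=d.get("vasoactive_drugs"),
            cpr=d.get("cpr"),
            lactate=d.get("lactate"),
            ph=d.get("ph"),
        ),
        respiratory=Respiratory(
            acute_cyanosis=d.get("acute_cyanosis"),
            gasping=d.get("gasping"),
            respiratory_rate=d.get("respiratory_rate"),
            intubation_non_anesthesia=d.get("intubation_non_anesthesia"),
            hypoxemia_spo2_lt90_ge60min=d.get("hypoxemia"),
            pao2_fio2=d.get("pao2_fio2"),
        ),
        renal=Renal(
            oliguria_nonresponsive=d.get("oliguria"),
            dialysis_acute=d.get("dialysis"),
            creatinine=d.get("creatinine"),
        ),
        coagulation=Coagulation(
            failure_to_form_clots=d.get("failure_to_form_clots"),
            platelets=d.get("platelets"),
        ),
        hepatic=Hepatic(
            jaundice_with_preeclampsia=d.get("jaundice"),
            bilirubin=d.get("bilirubin"),
        ),
        neurologic=Neurologic(
            unconscious_ge12h=d.get("unconscious"),
            stroke=d.get("stroke"),
            uncontrollable_fits_status_epilepticus=d.get("fits"),
            total_paralysis=d.get("paralysis"),
        ),
        uterine=Uterine(hysterectomy_for_hemorrhage_or_infection=d.get("hysterectomy")),
    )


def random_grid_record(rng) -> dict:
    """One random assignment from the discretized marker grid."""
    d = {k: rng.choice([None, False, True]) for k in FLAG_KEYS}
    for key, values in LAB_GRID.items():
        d[key] = values[rng.integers(0, len(values))]
    return d
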