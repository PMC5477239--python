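"""The WHO Maternal Near Miss criteria catalog.

Sixteen criteria in three groups:

* **A (disease-based)** — five severe complications / potentially
  life-threatening conditions (A0–A4);
* **B (intervention-based)** — four critical interventions or ICU
  admission (B0–B3);
* **C (organ-dysfunction-based)** — seven life-threatening organ
  dysfunctions (C0–C6). Meeting any C criterion defines the case as
  life-threatening, hence maternal near miss (if she survived) under the
  WHO approach.

Each criterion is a disjunction of clauses over a :class:`~nearmiss.records.
PatientRecord`. Clauses are pure and missing-safe: an unrecorded marker makes
the clause false, never an error. The catalog is the single source of truth
for thresholds; :func:`catalog_table` exports it as a machine-readable table
shared by documentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import pandas as pd

from .records import PatientRecord, ToolConfig

__all__ = [
    "Clause",
    "Criterion",
    "CATALOG",
    "CRITERION_IDS",
    "GROUPS",
    "NA",
    "NotApplicable",
    "criterion",
    "criterion_intervention",
    "evaluate_criterion",
    "catalog_table",
]


class NotApplicable:
    """Singleton outcome for a criterion that does not exist in a cohort.

    Falsy (so ``if evaluate_criterion(...)`` treats it like not-met) but
    distinguishable from ``False`` with ``result is NA``. A not-applicable
    criterion is excluded from a cohort's event denominators rather than
    counted as not met.
    """

    _instance: Optional["NotApplicable"] = None

    def __new__(cls) -> "NotApplicable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "N/A"


NA = NotApplicable()

Predicate = Callable[[PatientRecord, ToolConfig], bool]


@dataclass(frozen=True)
class Clause:
    """One disjunct of a criterion: a description and a pure predicate."""

    description: str
    predicate: Predicate

    def __call__(self, record: PatientRecord, config: ToolConfig) -> bool:
        return bool(self.predicate(record, config))


@dataclass(frozen=True)
class Criterion:
    id: str
    group: str
    label: str
    clauses: tuple[Clause, ...]

    def evaluate(self, record: PatientRecord, config: ToolConfig) -> bool:
        return any(clause(record, config) for clause in self.clauses)


def _flag(value: Optional[bool]) -> bool:
    # missing never evaluates as true
    return value is True


def _gt(value: Optional[float], threshold: float) -> bool:
    return value is not None and value > threshold


def _lt(value: Optional[float], threshold: float) -> bool:
    return value is not None and value < threshold


def _ge(value: Optional[float], threshold: float) -> bool:
    return value is not None and value >= threshold


CATALOG: tuple[Criterion, ...] = (
    Criterion(
        "A0",
        "A",
        "Severe postpartum hemorrhage",
        (Clause("severe postpartum hemorrhage", lambda r, c: _flag(r.conditions.severe_pph)),),
    ),
    Criterion(
        "A1",
        "A",
        "Severe pre-eclampsia",
        (Clause("severe pre-eclampsia", lambda r, c: _flag(r.conditions.severe_preeclampsia)),),
    ),
    Criterion(
        "A2",
        "A",
        "Eclampsia",
        (Clause("eclampsia", lambda r, c: _flag(r.conditions.eclampsia)),),
    ),
    Criterion(
        "A3",
        "A",
        "Sepsis or severe systemic infection",
        (
            Clause(
                "sepsis or severe systemic infection",
                lambda r, c: _flag(r.conditions.sepsis_severe_infection),
            ),
        ),
    ),
    Criterion(
        "A4",
        "A",
        "Ruptured uterus",
        (Clause("ruptured uterus", lambda r, c: _flag(r.conditions.uterine_rupture)),),
    ),
    Criterion(
        "B0",
        "B",
        "Use of blood products",
        # any transfusion counts; derived from units_blood so B0 and C3's
        # massive-transfusion clause can never disagree
        (Clause("any blood transfusion (>=1 unit)", lambda r, c: _ge(r.units_blood, 1)),),
    ),
    Criterion(
        "B1",
        "B",
        "Interventional radiology",
        (
            Clause(
                "interventional radiology (uterine artery embolization)",
                lambda r, c: _flag(r.interventions.interventional_radiology),
            ),
        ),
    ),
    Criterion(
        "B2",
        "B",
        "Laparotomy (other than caesarean section)",
        (
            Clause(
                "laparotomy other than caesarean section",
                lambda r, c: _flag(r.interventions.laparotomy_non_cs),
            ),
        ),
    ),
    Criterion(
        "B3",
        "B",
        "Admission to intensive care unit",
        (Clause("ICU admission", lambda r, c: _flag(r.interventions.icu_admission)),),
    ),
    Criterion(
        "C0",
        "C",
        "Cardiovascular dysfunction",
        (
            Clause("shock", lambda r, c: _flag(r.cardiovascular.shock)),
            Clause("cardiac arrest", lambda r, c: _flag(r.cardiovascular.cardiac_arrest)),
            Clause(
                "use of continuous vasoactive drugs",
                lambda r, c: _flag(r.cardiovascular.vasoactive_drugs),
            ),
            Clause("cardiopulmonary resuscitation", lambda r, c: _flag(r.cardiovascular.cpr)),
            Clause(
                "severe hypoperfusion (lactate > 5 mmol/l)",
                lambda r, c: _gt(r.cardiovascular.lactate, 5.0),
            ),
            Clause("severe acidosis (pH < 7.1)", lambda r, c: _lt(r.cardiovascular.ph, 7.1)),
        ),
    ),
    Criterion(
        "C1",
        "C",
        "Respiratory dysfunction",
        (
            Clause("acute cyanosis", lambda r, c: _flag(r.respiratory.acute_cyanosis)),
            Clause("gasping", lambda r, c: _flag(r.respiratory.gasping)),
            Clause(
                "severe tachypnea (respiratory rate > 40/min)",
                lambda r, c: _gt(r.respiratory.respiratory_rate, 40.0),
            ),
            Clause(
                "severe bradypnea (respiratory rate < 6/min)",
                lambda r, c: _lt(r.respiratory.respiratory_rate, 6.0),
            ),
            Clause(
                "intubation and ventilation not related to anesthesia",
                lambda r, c: _flag(r.respiratory.intubation_non_anesthesia),
            ),
            Clause(
                "severe hypoxemia (SpO2 < 90% for >= 60 min)",
                lambda r, c: _flag(r.respiratory.hypoxemia_spo2_lt90_ge60min),
            ),
            Clause(
                "severe hypoxemia (PaO2/FiO2 < 200)",
                lambda r, c: _lt(r.respiratory.pao2_fio2, 200.0),
            ),
        ),
    ),
    Criterion(
        "C2",
        "C",
        "Renal dysfunction",
        (
            Clause(
                "oliguria non-responsive to fluids or diuretics",
                lambda r, c: _flag(r.renal.oliguria_nonresponsive),
            ),
            Clause("dialysis for acute renal failure", lambda r, c: _flag(r.renal.dialysis_acute)),
            Clause(
                "severe acute azotemia (creatinine >= 300 umol/l)",
                lambda r, c: _ge(r.renal.creatinine, 300.0),
            ),
        ),
    ),
    Criterion(
        "C3",
        "C",
        "Coagulation/hematologic dysfunction",
        (
            Clause(
                "failure to form clots",
                lambda r, c: _flag(r.coagulation.failure_to_form_clots),
            ),
            Clause(
                "massive transfusion of blood or red cells (>= threshold units)",
                lambda r, c: _ge(r.units_blood, c.massive_transfusion_threshold),
            ),
            Clause(
                "severe acute thrombocytopenia (< 50,000 platelets/ml)",
                lambda r, c: _lt(r.coagulation.platelets, 50_000.0),
            ),
        ),
    ),
    Criterion(
        "C4",
        "C",
        "Hepatic dysfunction",
        (
            Clause(
                "jaundice in the presence of pre-eclampsia",
                lambda r, c: _flag(r.hepatic.jaundice_with_preeclampsia),
            ),
            Clause(
                "severe acute hyperbilirubinemia (bilirubin > 100 umol/l)",
                lambda r, c: _gt(r.hepatic.bilirubin, 100.0),
            ),
        ),
    ),
    Criterion(
        "C5",
        "C",
        "Neurologic dysfunction",
        (
            Clause(
                "prolonged unconsciousness/coma (>= 12 h)",
                lambda r, c: _flag(r.neurologic.unconscious_ge12h),
            ),
            Clause("stroke", lambda r, c: _flag(r.neurologic.stroke)),
            Clause(
                "uncontrollable fits / status epilepticus",
                lambda r, c: _flag(r.neurologic.uncontrollable_fits_status_epilepticus),
            ),
            Clause("total paralysis", lambda r, c: _flag(r.neurologic.total_paralysis)),
        ),
    ),
    Criterion(
        "C6",
        "C",
        "Uterine dysfunction/hysterectomy",
        (
            Clause(
                "uterine hemorrhage or infection leading to hysterectomy",
                lambda r, c: _flag(r.uterine.hysterectomy_for_hemorrhage_or_infection),
            ),
        ),
    ),
)

CRITERION_IDS: tuple[str, ...] = tuple(c.id for c in CATALOG)
GROUPS: tuple[str, ...] = ("A", "B", "C")

_BY_ID: dict[str, Criterion] = {c.id: c for c in CATALOG}

# B criteria disabled when the matching intervention is unavailable in a cohort.
# B0 is always applicable: any facility recording units of blood can report it.
_CRITERION_INTERVENTION: dict[str, str] = {
    "B1": "interventional_radiology",
    "B2": "laparotomy_non_cs",
    "B3": "icu_admission",
}


def criterion(criterion_id: str) -> Criterion:
    """Look up a criterion definition by id (A0..A4, B0..B3, C0..C6)."""
    try:
        return _BY_ID[criterion_id]
    except KeyError:
        raise KeyError(f"unknown criterion id: {criterion_id!r}") from None


def criterion_intervention(criterion_id: str) -> Optional[str]:
    """Name of the intervention a criterion depends on, or None."""
    return _CRITERION_INTERVENTION.get(criterion_id)


def evaluate_criterion(
    record: PatientRecord,
    criterion_id: str,
    config: ToolConfig | None = None,
) -> bool | NotApplicable:
    """Evaluate one WHO MNM criterion on one record.

    Returns ``True`` when any clause of the criterion is satisfied, ``False``
    otherwise; missing markers make clauses false. Returns the :data:`NA`
    sentinel when the criterion rests on an intervention that does not exist
    in the record's cohort (per ``config.available_interventions``).

    Raises
    ------
    KeyError
        If ``criterion_id`` is not in the catalog.
    """
    if config is None:
        config = ToolConfig()
    crit = criterion(criterion_id)
    needed = _CRITERION_INTERVENTION.get(criterion_id)
    if needed is not None and needed not in config.interventions_available(record.cohort_id):
        return NA
    return crit.evaluate(record, config)


def catalog_table() -> pd.DataFrame:
    """The criteria catalog as a tidy table, one row per clause.

    Columns: criterion id, group, criterion label, clause description.
    Documentation and tests read thresholds from here rather than restating
    them.
    """
    rows = [
        {"id": c.id, "group": c.group, "label": c.label, "clause": clause.description}
        for c in CATALOG
        for clause in c.clauses
    ]
    return pd.DataFrame(rows, columns=["id", "group", "label", "clause"])
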