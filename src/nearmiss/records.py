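"""Patient records and classification configuration.

A :class:`PatientRecord` holds everything the WHO Maternal Near Miss (MNM)
tool needs to classify one woman: demographics, outcome, the five
(potentially) life-threatening conditions, the critical interventions,
and the organ-dysfunction markers grouped by organ system. Every clinical
flag is tri-state (``True`` / ``False`` / ``None``): ``None`` means the
marker was not recorded, and a missing marker never satisfies a criterion
clause.

Laboratory values are stored in fixed canonical units — creatinine and
bilirubin in µmol/l, lactate in mmol/l, platelets per ml — and
:func:`creatinine_mgdl_to_umol` and friends convert conventional (mg/dl)
inputs at entry.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Setting",
    "Conditions",
    "Interventions",
    "Cardiovascular",
    "Respiratory",
    "Renal",
    "Coagulation",
    "Hepatic",
    "Neurologic",
    "Uterine",
    "Extras",
    "PatientRecord",
    "ToolConfig",
    "ALL_INTERVENTIONS",
    "CREATININE_UMOL_PER_MGDL",
    "BILIRUBIN_UMOL_PER_MGDL",
    "LACTATE_MGDL_PER_MMOL",
    "creatinine_mgdl_to_umol",
    "bilirubin_mgdl_to_umol",
    "lactate_mgdl_to_mmol",
]

# mg/dl -> µmol/l (creatinine, bilirubin); mg/dl -> mmol/l (lactate, divide)
CREATININE_UMOL_PER_MGDL = 88.4
BILIRUBIN_UMOL_PER_MGDL = 17.1
LACTATE_MGDL_PER_MMOL = 9.0


def creatinine_mgdl_to_umol(value: float) -> float:
    """Convert a creatinine concentration from mg/dl to µmol/l."""
    return value * CREATININE_UMOL_PER_MGDL


def bilirubin_mgdl_to_umol(value: float) -> float:
    """Convert a bilirubin concentration from mg/dl to µmol/l."""
    return value * BILIRUBIN_UMOL_PER_MGDL


def lactate_mgdl_to_mmol(value: float) -> float:
    """Convert a lactate concentration from mg/dl to mmol/l."""
    return value / LACTATE_MGDL_PER_MMOL


class Setting(str, enum.Enum):
    """Resource level of the setting a woman received care in."""

    high_resource = "high_resource"
    low_resource = "low_resource"


class _Markers(BaseModel):
    """Base for marker groups: frozen, no extra fields, missing-aware."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    def all_missing(self) -> bool:
        return all(v is None for v in self.__dict__.values())


class Conditions(_Markers):
    """Disease-based (group A) condition flags."""

    severe_pph: Optional[bool] = None
    severe_preeclampsia: Optional[bool] = None
    eclampsia: Optional[bool] = None
    sepsis_severe_infection: Optional[bool] = None
    uterine_rupture: Optional[bool] = None


class Interventions(_Markers):
    """Critical-intervention (group B) flags other than blood products.

    Use of blood products (B0) is derived from ``units_blood`` and has no
    separate flag, so B0 can never contradict the transfusion clause of C3.
    """

    interventional_radiology: Optional[bool] = None
    laparotomy_non_cs: Optional[bool] = None
    icu_admission: Optional[bool] = None


class Cardiovascular(_Markers):
    shock: Optional[bool] = None
    cardiac_arrest: Optional[bool] = None
    vasoactive_drugs: Optional[bool] = None
    cpr: Optional[bool] = None
    lactate: Optional[float] = Field(default=None, ge=0)  # mmol/l
    ph: Optional[float] = Field(default=None, gt=6.0, lt=8.0)


class Respiratory(_Markers):
    acute_cyanosis: Optional[bool] = None
    gasping: Optional[bool] = None
    respiratory_rate: Optional[float] = Field(default=None, ge=0)  # breaths/min
    intubation_non_anesthesia: Optional[bool] = None
    hypoxemia_spo2_lt90_ge60min: Optional[bool] = None
    pao2_fio2: Optional[float] = Field(default=None, gt=0, lt=700)


class Renal(_Markers):
    oliguria_nonresponsive: Optional[bool] = None
    dialysis_acute: Optional[bool] = None
    creatinine: Optional[float] = Field(default=None, ge=0)  # µmol/l


class Coagulation(_Markers):
    failure_to_form_clots: Optional[bool] = None
    platelets: Optional[float] = Field(default=None, ge=0)  # per ml


class Hepatic(_Markers):
    jaundice_with_preeclampsia: Optional[bool] = None
    bilirubin: Optional[float] = Field(default=None, ge=0)  # µmol/l


class Neurologic(_Markers):
    unconscious_ge12h: Optional[bool] = None
    stroke: Optional[bool] = None
    uncontrollable_fits_status_epilepticus: Optional[bool] = None
    total_paralysis: Optional[bool] = None


class Uterine(_Markers):
    hysterectomy_for_hemorrhage_or_infection: Optional[bool] = None


class Extras(_Markers):
    """Markers used only by the local severe-maternal-outcome inclusion rules."""

    hemoglobin: Optional[float] = Field(default=None, ge=0)  # g/dl
    estimated_blood_loss: Optional[float] = Field(default=None, ge=0)  # ml
    iv_antimicrobials: Optional[bool] = None
    clinician_judged_severe: Optional[bool] = None


class PatientRecord(BaseModel):
    """One woman's record, as collected by a severe-maternal-outcome audit.

    All marker groups default to entirely missing, so minimal records
    (``PatientRecord(cohort_id="NL", setting="high_resource", died=False)``)
    are valid and classify as meeting no criteria.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    cohort_id: str
    setting: Setting
    died: bool
    age_years: Optional[float] = Field(default=None, ge=0)
    parity: Optional[int] = Field(default=None, ge=0)
    units_blood: Optional[int] = Field(default=None, ge=0)
    conditions: Conditions = Conditions()
    interventions: Interventions = Interventions()
    cardiovascular: Cardiovascular = Cardiovascular()
    respiratory: Respiratory = Respiratory()
    renal: Renal = Renal()
    coagulation: Coagulation = Coagulation()
    hepatic: Hepatic = Hepatic()
    neurologic: Neurologic = Neurologic()
    uterine: Uterine = Uterine()
    extras: Extras = Extras()

    # --- per-group missingness -------------------------------------------
    def group_a_all_missing(self) -> bool:
        """True when none of the five condition flags was recorded."""
        return self.conditions.all_missing()

    def group_b_all_missing(self) -> bool:
        """True when neither transfusion units nor any intervention flag was recorded."""
        return self.units_blood is None and self.interventions.all_missing()

    def group_c_all_missing(self) -> bool:
        """True when no organ-dysfunction marker (nor transfusion units) was recorded."""
        return self.units_blood is None and all(
            g.all_missing()
            for g in (
                self.cardiovascular,
                self.respiratory,
                self.renal,
                self.coagulation,
                self.hepatic,
                self.neurologic,
                self.uterine,
            )
        )


ALL_INTERVENTIONS = frozenset(
    {"interventional_radiology", "laparotomy_non_cs", "icu_admission"}
)


class ToolConfig(BaseModel):
    """Tunable parameters of the MNM classification.

    Parameters
    ----------
    massive_transfusion_threshold:
        Units of blood/red cells defining the "massive transfusion" clause of
        C3 (coagulation/haematologic dysfunction). The WHO tool uses 5.
    any_transfusion_low_resource:
        When True, every low-resource woman who received >= 1 unit of blood is
        included in the life-threatening population, on top of the
        organ-dysfunction criteria. This is the "corrected" analysis used to
        compensate for restricted blood availability in low-resource settings.
    available_interventions:
        Per-cohort subset of interventions that exist locally. A cohort absent
        from the mapping has every intervention available. An unavailable
        intervention makes the matching B criterion *not applicable* in that
        cohort (distinct from false), and it is excluded from that cohort's
        intervention-event denominators. Group A and group C evaluation never
        depend on availability; C3's transfusion clause depends only on
        ``units_blood``.
    """

    model_config = ConfigDict(frozen=True)

    massive_transfusion_threshold: int = Field(default=5, ge=1)
    any_transfusion_low_resource: bool = False
    available_interventions: dict[str, frozenset[str]] = Field(default_factory=dict)
    unit_conversions: dict[str, float] = Field(
        default_factory=lambda: {
            "creatinine_umol_per_mgdl": CREATININE_UMOL_PER_MGDL,
            "bilirubin_umol_per_mgdl": BILIRUBIN_UMOL_PER_MGDL,
            "lactate_mgdl_per_mmol": LACTATE_MGDL_PER_MMOL,
        }
    )

    @model_validator(mode="after")
    def _check_interventions(self) -> "ToolConfig":
        for cohort, avail in self.available_interventions.items():
            unknown = set(avail) - ALL_INTERVENTIONS
            if unknown:
                raise ValueError(
                    f"unknown interventions for cohort {cohort!r}: {sorted(unknown)}"
                )
        return self

    def interventions_available(self, cohort_id: str) -> frozenset[str]:
        """Interventions available in ``cohort_id`` (default: all of them)."""
        return self.available_interventions.get(cohort_id, ALL_INTERVENTIONS)
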