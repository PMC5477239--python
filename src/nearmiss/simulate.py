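"""Seedable synthetic cohorts with the statistical structure of the three studies.

The original patient-level data were never deposited, so end-to-end testing
of the classification and comparison pipeline relies on synthetic cohorts.
A :class:`SyntheticCohortSpec` captures what the published aggregates pin
down — banded age/parity/transfusion distributions, per-criterion event
prevalences, group-level detection rates, overall and life-threatening case
fatality, and per-variable missingness — and :func:`generate_cohort` samples
patient records from it reproducibly.

The published aggregates are mutually inconsistent under marker independence
(disease criteria are nearly mutually exclusive; organ-dysfunction markers
overlap strongly with massive transfusion), so the generator induces a
minimal dependence structure:

* **group A** — a per-woman disease count (0, 1 or 2) chosen so that both
  the group detection rate and the total event count match, with diseases
  assigned by relative frequency;
* **groups B and C** — the transfusion-derived "driver" clauses (B0 = any
  transfusion; C3's massive-transfusion clause) come straight from the
  sampled units of blood, and the remaining markers are drawn conditionally
  on the driver so that each marker's marginal prevalence is preserved while
  the group detection rate is met exactly in expectation;
* **mortality** — death is sampled conditionally on organ-dysfunction status
  to realise the overall and life-threatening case fatality rates.

Cross-criterion correlations beyond these mechanisms (e.g. PPH with
hysterectomy) are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from . import published
from .catalog import CRITERION_IDS
from .classify import classify_cohort
from .records import (
    Cardiovascular,
    Coagulation,
    Conditions,
    Hepatic,
    Interventions,
    Neurologic,
    PatientRecord,
    Renal,
    Respiratory,
    Setting,
    ToolConfig,
    Uterine,
)

__all__ = [
    "SyntheticCohortSpec",
    "preset_specs",
    "generate_cohort",
    "recover_parameters",
    "implied_prevalences",
    "implied_group_rates",
]

_A_IDS = ("A0", "A1", "A2", "A3", "A4")
_B_MARKER_IDS = ("B1", "B2", "B3")
_C_OTHER_IDS = ("C0", "C1", "C2", "C4", "C5", "C6")

# representative marker set per sampled criterion
_A_FLAG = {
    "A0": "severe_pph",
    "A1": "severe_preeclampsia",
    "A2": "eclampsia",
    "A3": "sepsis_severe_infection",
    "A4": "uterine_rupture",
}
_B_FLAG = {
    "B1": "interventional_radiology",
    "B2": "laparotomy_non_cs",
    "B3": "icu_admission",
}


class SyntheticCohortSpec(BaseModel):
    """Generative parameters for one emulated cohort.

    ``criterion_prevalences`` holds each criterion's marginal probability
    (the published events-per-woman fraction); ``None`` marks criteria not
    applicable in the cohort. ``group_targets`` are the probabilities of
    fulfilling at least one criterion per group — the quantities the
    generator calibrates to.
    """

    model_config = ConfigDict(frozen=True)

    cohort_id: str
    setting: Setting
    n_women: int = Field(ge=0)
    age_band_probs: tuple[float, float, float]
    parity_band_probs: tuple[float, float, float]
    units_blood_probs: tuple[float, float, float, float, float, float]
    group_targets: dict[str, float]
    criterion_prevalences: dict[str, Optional[float]]
    cfr_overall: float = Field(ge=0, le=1)
    cfr_life_threatening: Optional[float] = Field(default=None, ge=0, le=1)
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: {"age_years": 0.0, "parity": 0.0, "units_blood": 0.0}
    )

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticCohortSpec":
        for name in ("age_band_probs", "parity_band_probs", "units_blood_probs"):
            probs = getattr(self, name)
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(probs)!r})")
        for g in ("A", "B", "C"):
            if g not in self.group_targets:
                raise ValueError(f"group_targets missing group {g!r}")
            if not 0.0 <= self.group_targets[g] <= 1.0:
                raise ValueError(f"group target {g} must lie in [0, 1]")
        for cid, p in self.criterion_prevalences.items():
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {cid} must lie in [0, 1]")
        for var, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate of {var} must lie in [0, 1]")
        if (
            self.cfr_life_threatening is not None
            and self.cfr_life_threatening < self.cfr_overall
        ):
            raise ValueError(
                "cfr_life_threatening must be >= cfr_overall when both are set"
            )
        return self

    def prevalence(self, criterion_id: str) -> float:
        p = self.criterion_prevalences.get(criterion_id)
        return 0.0 if p is None else p


# --------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class _Calibration:
    """Internal sampling parameters derived from a spec."""

    a_count_probs: tuple[float, float, float]  # P(0, 1, 2 diseases)
    a_weights: dict[str, float]
    f_b0: float                               # P(any transfusion recorded)
    b_cond: dict[str, tuple[float, float]]    # id -> (P(.|B0), P(.|not B0))
    c3_extra: float                           # clot-marker prob (indep. of units)
    f_c3: float                               # P(C3 met)
    c_cond: dict[str, tuple[float, float]]    # id -> (P(.|C3), P(.|not C3))
    p_death_c: float
    p_death_not_c: float


def _solve_conditional(
    marginals: dict[str, float], driver_prob: float, group_target: float
) -> dict[str, tuple[float, float]]:
    """Per-marker conditional probabilities (given driver / not driver).

    Chosen so that each marker keeps its marginal prevalence while
    ``P(driver or any marker) == group_target``. When the driver alone
    already exceeds the target the markers go fully inside the driver
    (the group rate then floors at the driver rate).
    """
    ids = [i for i, p in marginals.items() if p > 0]
    rhs = (1.0 - group_target) / (1.0 - driver_prob) if driver_prob < 1 else 1.0
    out: dict[str, tuple[float, float]] = {i: (0.0, 0.0) for i in marginals}
    if rhs >= 1.0:
        # target at or below the driver-only rate: nest markers inside driver
        for i in ids:
            a = min(1.0, marginals[i] / driver_prob) if driver_prob > 0 else 0.0
            out[i] = (a, 0.0)
        return out
    if not ids:
        raise ValueError("group target unattainable: no markers to calibrate")

    pvec = np.array([marginals[i] for i in ids])

    def g(s: float) -> float:
        return float(np.prod(1.0 - np.minimum(1.0, s * pvec))) - rhs

    hi = 1.0 / pvec.max()
    if g(hi) > 0:  # even saturating a marker cannot reach the target
        raise ValueError("group target unattainable with the given marginals")
    s = brentq(g, 0.0, hi, xtol=1e-12) if g(0.0) > 0 else 0.0
    for i in ids:
        b = min(1.0, s * marginals[i])
        if driver_prob > 0:
            a = (marginals[i] - b * (1.0 - driver_prob)) / driver_prob
            a = min(1.0, max(0.0, a))
        else:
            a = b
        out[i] = (a, b)
    return out


def _calibrate(spec: SyntheticCohortSpec) -> _Calibration:
    miss_u = spec.missingness_rates.get("units_blood", 0.0)
    f_b0 = (1.0 - spec.units_blood_probs[0]) * (1.0 - miss_u)
    f_auto_c3 = spec.units_blood_probs[5] * (1.0 - miss_u)

    # group A: disease count per woman matching detection rate and event total
    t_a = spec.group_targets["A"]
    p_a = {i: spec.prevalence(i) for i in _A_IDS}
    m_a = sum(p_a.values())
    if m_a > 2.0 * t_a + 1e-12:
        raise ValueError("group A marginals require >2 diseases per woman")
    p2 = min(t_a, max(0.0, m_a - t_a))
    p1 = t_a - p2
    weights = {i: (p / m_a if m_a > 0 else 0.0) for i, p in p_a.items()}

    b_cond = _solve_conditional(
        {i: spec.prevalence(i) for i in _B_MARKER_IDS}, f_b0, spec.group_targets["B"]
    )

    m_c3 = spec.prevalence("C3")
    if f_auto_c3 < 1.0:
        c3_extra = max(0.0, 1.0 - (1.0 - m_c3) / (1.0 - f_auto_c3))
    else:
        c3_extra = 0.0
    f_c3 = 1.0 - (1.0 - f_auto_c3) * (1.0 - c3_extra)
    c_cond = _solve_conditional(
        {i: spec.prevalence(i) for i in _C_OTHER_IDS}, f_c3, spec.group_targets["C"]
    )

    p_c = spec.group_targets["C"]
    cfr_lt = spec.cfr_life_threatening if spec.cfr_life_threatening is not None else spec.cfr_overall
    p_death_c = min(1.0, cfr_lt)
    if p_c < 1.0:
        p_death_not_c = (spec.cfr_overall - p_death_c * p_c) / (1.0 - p_c)
        p_death_not_c = min(1.0, max(0.0, p_death_not_c))
    else:
        p_death_not_c = 0.0
    return _Calibration(
        a_count_probs=(1.0 - t_a, p1, p2),
        a_weights=weights,
        f_b0=f_b0,
        b_cond=b_cond,
        c3_extra=c3_extra,
        f_c3=f_c3,
        c_cond=c_cond,
        p_death_c=p_death_c,
        p_death_not_c=p_death_not_c,
    )


def implied_prevalences(spec: SyntheticCohortSpec) -> dict[str, Optional[float]]:
    """Model-implied marginal probability of meeting each criterion.

    These are the quantities :func:`generate_cohort` realises (and
    :func:`recover_parameters` recovers); they equal the spec's stored
    prevalences up to the clamping needed to honour group targets and the
    units-of-blood distribution.
    """
    cal = _calibrate(spec)
    out: dict[str, Optional[float]] = {}
    p0, p1, p2 = cal.a_count_probs
    w = cal.a_weights
    for i in _A_IDS:
        pair = w[i] + sum(
            w[j] * w[i] / (1.0 - w[j]) for j in _A_IDS if j != i and w[j] < 1.0
        )
        out[i] = p1 * w[i] + p2 * min(1.0, pair)
    out["B0"] = cal.f_b0
    for i in _B_MARKER_IDS:
        if spec.criterion_prevalences.get(i) is None:
            out[i] = None
        else:
            a, b = cal.b_cond[i]
            out[i] = a * cal.f_b0 + b * (1.0 - cal.f_b0)
    out["C3"] = cal.f_c3
    for i in _C_OTHER_IDS:
        a, b = cal.c_cond[i]
        out[i] = a * cal.f_c3 + b * (1.0 - cal.f_c3)
    return out


def implied_group_rates(spec: SyntheticCohortSpec) -> dict[str, float]:
    """Model-implied probability of fulfilling >=1 criterion per group."""
    cal = _calibrate(spec)
    rate_a = cal.a_count_probs[1] + cal.a_count_probs[2]
    none_b = (1.0 - cal.f_b0) * math.prod(1.0 - b for _, b in cal.b_cond.values())
    none_c = (1.0 - cal.f_c3) * math.prod(1.0 - b for _, b in cal.c_cond.values())
    return {"A": rate_a, "B": 1.0 - none_b, "C": 1.0 - none_c}


# --------------------------------------------------------------------------
# presets


def preset_specs() -> dict[str, SyntheticCohortSpec]:
    """Specs emulating the Dutch (NL), Tanzanian (TZ) and Malawian (MW) cohorts.

    Band probabilities equal the published cohort proportions (among women
    with the variable recorded); criterion prevalences equal the published
    events-per-woman fractions; group targets equal the published detection
    rates; missingness matches the published "data available" gaps.
    """
    specs: dict[str, SyntheticCohortSpec] = {}
    for cohort in published.COHORTS:
        n = published.COHORT_N[cohort]

        def probs(counts: dict[str, int], avail: int) -> tuple[float, ...]:
            return tuple(c / avail for c in counts.values())

        age_avail = published.DATA_AVAILABLE["age"][cohort]
        parity_avail = published.DATA_AVAILABLE["parity"][cohort]
        units_avail = published.DATA_AVAILABLE["units_blood"][cohort]
        prevalences = {
            cid: (None if counts[cohort] is None else counts[cohort] / n)
            for cid, counts in published.EVENT_COUNTS.items()
        }
        lt_n = published.GROUP_DETECTION["C"][cohort]
        specs[cohort] = SyntheticCohortSpec(
            cohort_id=cohort,
            setting=Setting(published.SETTINGS[cohort]),
            n_women=n,
            age_band_probs=probs(dict(published.AGE_BAND_COUNTS[cohort]), age_avail),
            parity_band_probs=probs(dict(published.PARITY_BAND_COUNTS[cohort]), parity_avail),
            units_blood_probs=probs(dict(published.UNITS_BAND_COUNTS[cohort]), units_avail),
            group_targets={
                g: published.GROUP_DETECTION[g][cohort] / n for g in ("A", "B", "C")
            },
            criterion_prevalences=prevalences,
            cfr_overall=published.DEATHS[cohort] / n,
            cfr_life_threatening=published.LIFE_THREATENING_DEATHS[cohort] / lt_n,
            missingness_rates={
                "age_years": 1.0 - age_avail / n,
                "parity": 1.0 - parity_avail / n,
                "units_blood": 1.0 - units_avail / n,
            },
        )
    return specs


def preset_tool_config(**overrides) -> ToolConfig:
    """Tool configuration matching the three studies' local facilities."""
    return ToolConfig(
        available_interventions=dict(published.AVAILABLE_INTERVENTIONS), **overrides
    )


# --------------------------------------------------------------------------
# generation


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> list[PatientRecord]:
    """Sample a cohort of ``spec.n_women`` records; same seed, same cohort.

    Records are sampled independently of one another. Within a record the
    only dependencies are the calibrated ones described in the module
    docstring. Banded draws are materialised as concrete values (e.g. age
    band 20–35 becomes a uniform integer in the band) so records pass type
    validation.
    """
    cal = _calibrate(spec)  # validates attainability before any sampling
    rng = np.random.default_rng(seed)
    n = spec.n_women
    if n == 0:
        return []

    age_idx = rng.choice(3, size=n, p=spec.age_band_probs)
    age_lo = rng.integers(16, 20, size=n)
    age_mid = rng.integers(20, 36, size=n)
    age_hi = rng.integers(36, 46, size=n)
    age_val = np.select([age_idx == 0, age_idx == 1], [age_lo, age_mid], age_hi)
    age_missing = rng.random(n) < spec.missingness_rates.get("age_years", 0.0)

    parity_idx = rng.choice(3, size=n, p=spec.parity_band_probs)
    parity_multi = rng.integers(2, 7, size=n)
    parity_val = np.select([parity_idx == 0, parity_idx == 1], [0, 1], parity_multi)
    parity_missing = rng.random(n) < spec.missingness_rates.get("parity", 0.0)

    units_idx = rng.choice(6, size=n, p=spec.units_blood_probs)
    units_massive = rng.integers(5, 9, size=n)
    units_val = np.where(units_idx == 5, units_massive, units_idx)
    units_missing = rng.random(n) < spec.missingness_rates.get("units_blood", 0.0)

    a_ids = list(_A_IDS)
    a_w = np.array([cal.a_weights[i] for i in a_ids])
    a_count = rng.choice(3, size=n, p=cal.a_count_probs)

    b_u = {i: rng.random(n) for i in _B_MARKER_IDS}
    clot_u = rng.random(n)
    c_u = {i: rng.random(n) for i in _C_OTHER_IDS}
    death_u = rng.random(n)

    available = set(
        i for i in _B_MARKER_IDS if spec.criterion_prevalences.get(i) is not None
    )

    records: list[PatientRecord] = []
    for k in range(n):
        units: Optional[int] = None if units_missing[k] else int(units_val[k])
        b0 = units is not None and units >= 1
        auto_c3 = units is not None and units >= 5

        diseases = set()
        if a_count[k] > 0 and a_w.sum() > 0:
            diseases = set(rng.choice(a_ids, size=a_count[k], replace=False, p=a_w))
        cond_flags = {flag: (cid in diseases) for cid, flag in _A_FLAG.items()}

        interv_flags: dict[str, Optional[bool]] = {}
        for i in _B_MARKER_IDS:
            if i not in available:
                interv_flags[_B_FLAG[i]] = None
            else:
                a, b = cal.b_cond[i]
                interv_flags[_B_FLAG[i]] = bool(b_u[i][k] < (a if b0 else b))

        clot = bool(clot_u[k] < cal.c3_extra)
        c3 = clot or auto_c3
        c_flags = {}
        for i in _C_OTHER_IDS:
            a, b = cal.c_cond[i]
            c_flags[i] = bool(c_u[i][k] < (a if c3 else b))
        group_c = c3 or any(c_flags.values())

        died = bool(death_u[k] < (cal.p_death_c if group_c else cal.p_death_not_c))

        records.append(
            PatientRecord(
                cohort_id=spec.cohort_id,
                setting=spec.setting,
                died=died,
                age_years=None if age_missing[k] else float(age_val[k]),
                parity=None if parity_missing[k] else int(parity_val[k]),
                units_blood=units,
                conditions=Conditions(**cond_flags),
                interventions=Interventions(**interv_flags),
                cardiovascular=Cardiovascular(shock=c_flags["C0"]),
                respiratory=Respiratory(acute_cyanosis=c_flags["C1"]),
                renal=Renal(oliguria_nonresponsive=c_flags["C2"]),
                coagulation=Coagulation(failure_to_form_clots=clot),
                hepatic=Hepatic(jaundice_with_preeclampsia=c_flags["C4"]),
                neurologic=Neurologic(unconscious_ge12h=c_flags["C5"]),
                uterine=Uterine(
                    hysterectomy_for_hemorrhage_or_infection=c_flags["C6"]
                ),
            )
        )
    return records


def recover_parameters(
    cohort: Sequence[PatientRecord], config: ToolConfig | None = None
) -> SyntheticCohortSpec:
    """Empirical :class:`SyntheticCohortSpec` of an observed cohort.

    Band frequencies are computed among women with the variable recorded;
    a variable recorded for nobody falls back to a uniform distribution.
    Criterion prevalences are the fractions of women meeting each criterion
    under ``config`` (``None`` where the criterion is not applicable);
    ``cfr_life_threatening`` is ``None`` when no woman meets a group-C
    criterion. Used for generate→recover round-trip checks.
    """
    if not cohort:
        raise ValueError("cannot recover parameters from an empty cohort")
    cfg = config if config is not None else ToolConfig()
    cohort_ids = {r.cohort_id for r in cohort}
    if len(cohort_ids) != 1:
        raise ValueError(f"records from multiple cohorts: {sorted(cohort_ids)}")
    n = len(cohort)
    results = classify_cohort(list(cohort), cfg)

    def band_freqs(values, n_bands, to_idx) -> tuple[float, ...]:
        present = [v for v in values if v is not None]
        if not present:
            return tuple(1.0 / n_bands for _ in range(n_bands))
        counts = [0] * n_bands
        for v in present:
            counts[to_idx(v)] += 1
        return tuple(c / len(present) for c in counts)

    ages = [r.age_years for r in cohort]
    parities = [r.parity for r in cohort]
    units = [r.units_blood for r in cohort]

    prevalences: dict[str, Optional[float]] = {}
    for cid in CRITERION_IDS:
        if all(cid in res.not_applicable for res in results):
            prevalences[cid] = None
        else:
            prevalences[cid] = sum(cid in res.met for res in results) / n

    group_targets = {
        "A": sum(r.group_a for r in results) / n,
        "B": sum(r.group_b for r in results) / n,
        "C": sum(r.group_c for r in results) / n,
    }
    deaths = sum(r.record.died for r in results)
    lt = [r for r in results if r.group_c]
    cfr_lt = (sum(r.record.died for r in lt) / len(lt)) if lt else None
    record = cohort[0]
    return SyntheticCohortSpec(
        cohort_id=record.cohort_id,
        setting=record.setting,
        n_women=n,
        age_band_probs=band_freqs(ages, 3, lambda a: 0 if a < 20 else (1 if a <= 35 else 2)),
        parity_band_probs=band_freqs(parities, 3, lambda p: min(p, 2)),
        units_blood_probs=band_freqs(units, 6, lambda u: min(u, 5)),
        group_targets=group_targets,
        criterion_prevalences=prevalences,
        cfr_overall=deaths / n,
        cfr_life_threatening=cfr_lt,
        missingness_rates={
            "age_years": sum(a is None for a in ages) / n,
            "parity": sum(p is None for p in parities) / n,
            "units_blood": sum(u is None for u in units) / n,
        },
    )
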