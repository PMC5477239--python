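# Methods

## The classification model

The WHO Maternal Near Miss (MNM) approach identifies women who *nearly died
but survived* a complication of pregnancy, childbirth or the 42 days after
termination of pregnancy. The tool classifies each woman against sixteen
criteria in three groups:

* **Group A — disease-based** (potentially life-threatening conditions):
  severe postpartum haemorrhage, severe pre-eclampsia, eclampsia,
  sepsis/severe systemic infection, ruptured uterus (A0–A4).
* **Group B — intervention-based** (critical interventions): use of blood
  products, interventional radiology, laparotomy other than caesarean
  section, ICU admission (B0–B3).
* **Group C — organ-dysfunction-based** (life-threatening conditions):
  cardiovascular, respiratory, renal, coagulation/haematologic, hepatic,
  neurologic and uterine dysfunction (C0–C6). Meeting any C criterion
  defines the case as *life-threatening*, hence MNM (or, with death, a
  severe maternal outcome).

Each criterion is a disjunction of clauses over a patient record
(`nearmiss.catalog` is the single source of truth; `catalog_table()` exports
it). Every clause comparison follows the printed inequality direction
exactly: ≥ 5 units transfused, platelets < 50,000/ml, respiratory rate > 40
or < 6 /min, creatinine ≥ 300 µmol/l, bilirubin > 100 µmol/l, pH < 7.1,
lactate > 5 mmol/l, PaO₂/FiO₂ < 200, SpO₂ < 90 % for ≥ 60 min. Canonical
internal units are µmol/l (creatinine, bilirubin), mmol/l (lactate) and
platelets per ml; converters for conventional units use the fixed factors
creatinine ×88.4, bilirubin ×17.1 (mg/dl → µmol/l) and lactate ÷9
(mg/dl → mmol/l). The renal threshold is stated once in the literature with
the unit "µmol/ml"; the mg/dl equivalent printed beside it confirms µmol/l
and that is what the engine uses.

**Missing data.** Every flag is tri-state (true / false / unrecorded) and a
missing marker makes its clause false, never an error. A record is flagged
*incomplete* when at least one criteria group has none of its markers
recorded, and *not assessable* (excluded from all denominators) when all
three groups are entirely unrecorded. The exclusion rule is this package's
own: registry audits exclude a small number of cases for insufficient data,
but no published rule states the precise condition, so the most conservative
one (no information at all) was chosen. No imputation is performed.

**Derived criteria.** B0 (use of blood products) is derived as
`units_blood >= 1` rather than stored as a flag, so it can never contradict
C3's massive-transfusion clause, which is `units_blood >=
massive_transfusion_threshold` (default 5, configurable ≥ 1). A woman
contributes at most one *event* per criterion: shock *and* CPR still yield a
single C0 event, matching how the published event tables tabulate
subcategories.

**Applicability.** Facilities differ: the Tanzanian site had no
interventional radiology, the Malawian site neither that nor an ICU.
`ToolConfig.available_interventions` maps cohorts to their available
interventions; an unavailable intervention makes the matching B criterion
*not applicable* — a distinct outcome, not "not met" — and removes it from
that cohort's intervention event denominators. Availability never affects
group A or C evaluation (C3's transfusion clause depends only on recorded
units).

**The correction analysis.** Where blood is scarce, transfusion of five
units is exceptional even in life-threatening haemorrhage, so the organ
dysfunction definition under-detects. With
`any_transfusion_low_resource=True`, every low-resource woman with ≥ 1 unit
transfused joins the life-threatening population (her group-C flag is
unchanged). Corrected and uncorrected analyses differ *only* in this toggle.

## Local SMO inclusion rules

The three cohorts recruited women by their own severe-maternal-outcome
definitions before the WHO tool was applied: the Dutch nationwide LEMMoN
study (ICU admission, uterine rupture, eclampsia/HELLP, major obstetric
haemorrhage at ≥ 4 units or embolization/hysterectomy, clinician judgement),
the Tanzanian Haydom study (a supplemented clinical-signs list, limited
laboratory criteria, uterine rupture, haemorrhage at ≥ 1 unit or
haemoglobin < 6 g/dl or blood loss > 1 l, severe infections) and the
Malawian 4M study (management-based criteria including any transfusion,
uterine rupture, eclampsia/severe pre-eclampsia, severe complications).
`nearmiss.inclusion` implements the three rule sets as pure, missing-safe
predicates and reports which groups matched. The published source table is
partly ambiguous about which fragments belong to which column; the
reconstruction here preserves every unambiguous anchor (the Dutch 4-unit
threshold, the Malawian any-transfusion rule, the Tanzanian haemoglobin
criterion) and assigns the remainder to the setting whose study design they
describe.

## Aggregation and comparison

Per-cohort summaries count women fulfilling ≥ 1 criterion per group
(denominator: assessable women), events per subcategory (denominator for
percentages: the cohort's group event total, as the published tables print),
banded characteristics — age < 20 / 20–35 / > 35 years, parity 0 / 1 / ≥ 2,
units of blood 0…4 / ≥ 5 — each over its own "data available" n, deaths and
the case fatality rate CFR = 100·deaths/n.

Percentages are rounded half-away-from-zero to one decimal, and to the
nearest integer for proportions of deaths; this convention reproduces every
published derived value recomputed here (87.2, 38.2, 46.0, the 7.8-point
increase, 35 %, 33 %). Pooled rates are ratio-of-sums, never averages of
percentages.

Between-cohort tests follow the original analysis: Pearson chi-square
without continuity correction for categorical tables and two-sided
pooled-variance t-tests for numeric variables, flagged `a` (p < 0.05) and
`b` (p < 0.0001) with no multiple-testing adjustment. Per-subcategory
chi-squares compare women *with* versus *without* the event across cohorts
(cohort sizes as denominators): this is the construction that reproduces
the published per-row p-values (ruptured uterus 0.11, ICU 0.78, renal
0.21), whereas event-total denominators do not. Rows not applicable in any
compared cohort are dropped; a zero marginal is an error naming the
category.

One published pooled figure is internally inconsistent: the
intervention-based total is printed as 2504 (78.9 %) while the per-cohort
counts sum to 2522 (79.5 %). The pipeline reports the sum. Likewise the
uncorrected life-threatening count appears both as 1211 and 1205; 1211 is
consistent with the per-cohort counts and is used throughout.

## Synthetic cohorts

`nearmiss.simulate` generates seedable cohorts whose structure matches the
published aggregates of the three studies, since the patient-level data were
never deposited. A spec fixes, per cohort: band probabilities equal to the
published proportions; per-criterion prevalences equal to the published
events-per-woman fractions; group-level detection targets; overall and
life-threatening CFR; and per-variable missingness equal to the published
"data available" gaps (missing completely at random).

The published marginals and group rates are mutually inconsistent under
marker independence — disease criteria are nearly mutually exclusive
(2638 events across 2308 Dutch group-A women), while organ-dysfunction
markers overlap strongly with massive transfusion. The generator therefore
induces a minimal dependence structure:

* **Group A**: each woman has 0, 1 or 2 diseases with
  P(≥1) = detection target and E[count] = sum of prevalences; diseases are
  assigned by relative frequency without replacement. Both the group rate
  and (to first order) the marginals are honoured; needing > 2 diseases per
  woman is rejected at calibration.
* **Groups B and C**: the transfusion-derived driver clauses (B0 = ≥ 1 unit;
  C3's ≥ 5-unit clause, topped up by a failure-to-form-clots marker to reach
  the C3 marginal) come directly from the sampled units of blood. The
  remaining markers are Bernoulli draws whose probabilities differ given
  driver / no driver, solved (scalar root-find) so that each marker keeps
  its marginal prevalence while the group detection probability equals the
  target exactly. `implied_prevalences` / `implied_group_rates` expose the
  resulting model-implied quantities, which the generate→recover round-trip
  tests verify to within three binomial standard errors at n = 10,000.
* **Mortality**: death is Bernoulli with probability `cfr_life_threatening`
  given any group-C marker and the complementary solved rate otherwise, so
  both CFR levels are realised in expectation (the invariant
  cfr_life_threatening ≥ cfr_overall is enforced when both are set).

What the presets do **not** emulate: cross-criterion clinical correlations
beyond the transfusion driver (e.g. PPH with hysterectomy), informative
missingness, within-hospital clustering, joint distributions of
characteristics within the life-threatening subset (only marginals are
published), or exact printed counts — a generated Tanzanian cohort's
*corrected* life-threatening fraction, for instance, falls short of the
published 91.9 % because the real overlap between transfusion and the
supplemented clinical criteria is unknowable from marginals. Passing
end-to-end tests therefore certify the pipeline's arithmetic and
invariances, not clinical realism of the joint distribution.

Band draws are materialised as concrete values (age 20–35 → uniform integer
in the band; units ≥ 5 → uniform in 5–8; parity ≥ 2 → uniform in 2–6).
Identical (spec, seed) pairs yield identical cohorts.

## Numerical and design choices

* Rounding: `decimal`-based half-away-from-zero on the value's shortest
  decimal representation, immune to binary float artefacts at the printed
  precisions.
* Calibration root-finds use Brent's method on [0, 1/max p] with xtol 1e-12;
  conditional probabilities are clamped to [0, 1] (clamping shifts a
  marginal only when a target is otherwise unattainable).
* Degenerate inputs: empty cohorts, zero-size populations and zero-variance
  t-tests raise; a cohort with zero deaths reports the
  deaths-without-organ-dysfunction percentage as absent rather than 0/0.
* The worked-example sizes used throughout tests (grid of 10⁴ marker
  assignments, recovery at n = 10,000 per cohort, preset-sized end-to-end
  runs) keep the full suite in well under a minute while leaving Monte-Carlo
  error far below the three-standard-error acceptance bands.

## Known limitations

The engine implements the WHO criteria table verbatim, including clauses
the original cohort studies may never have been able to evaluate; detection
on real registry data depends on what was actually recorded. Severe PPH
(A0) is a recorded clinical flag, not recomputed from blood-loss volume.
The inclusion rule sets are faithful to the published descriptions but
cannot recover operational details (e.g. how "two senior clinicians"
judgements were logged). Synthetic cohorts match marginals and group rates,
not joint distributions.
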