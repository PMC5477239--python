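"""Classify a single woman with the WHO Maternal Near Miss tool.

A woman with eclampsia who was admitted to ICU and remained unconscious
for over 12 hours meets one criterion in each group: the disease itself
(A2), the ICU admission (B3), and the neurologic organ dysfunction (C5).
Only the group-C criterion makes her case 'life-threatening' — and hence
a maternal near miss, since she survived — under the WHO approach.
"""

from nearmiss import PatientRecord, ToolConfig, check_smo_inclusion, classify_record, ruleset

woman = PatientRecord(
    cohort_id="NL",
    setting="high_resource",
    died=False,
    age_years=29,
    parity=1,
    units_blood=0,
    conditions={"eclampsia": True},
    interventions={"icu_admission": True},
    neurologic={"unconscious_ge12h": True},
)

result = classify_record(woman, ToolConfig())
print("criteria met:       ", sorted(result.met))
print("events:             ", list(result.events))
print("disease-based (A):  ", result.group_a)
print("intervention (B):   ", result.group_b)
print("organ dysfunction (C):", result.group_c)
print("life-threatening:   ", result.life_threatening)

# Would the Dutch LEMMoN study have recruited her as severe maternal outcome?
decision = check_smo_inclusion(woman, ruleset("netherlands_lemmon"))
print("LEMMoN inclusion:   ", decision.included, "via", list(decision.matched_groups))
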