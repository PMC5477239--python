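"""Per-woman classification with the WHO MNM tool."""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import CATALOG, NA, evaluate_criterion
from .records import PatientRecord, Setting, ToolConfig

__all__ = ["ClassificationResult", "classify_record", "classify_cohort"]


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying one woman with the WHO MNM tool.

    Attributes
    ----------
    met:
        Ids of all criteria the record satisfies.
    not_applicable:
        Ids of criteria that do not exist in the record's cohort (e.g. ICU
        admission where there is no ICU); these are excluded from event
        denominators rather than counted as not met.
    group_a, group_b, group_c:
        Whether at least one criterion of the group is met. Group C defines
        the WHO "life-threatening" condition.
    life_threatening:
        ``group_c``, optionally widened by the any-transfusion rule for
        low-resource settings (``ToolConfig.any_transfusion_low_resource``).
    events:
        One event per met criterion, in catalog order. A woman with several
        met criteria contributes several events; several positive markers
        within one criterion still yield a single event.
    incomplete:
        At least one criteria group had none of its markers recorded.
    assessable:
        False when *all three* groups had no markers recorded, in which case
        the record is excluded from classification denominators (mirroring
        cases excluded for insufficient data in registry audits).
    """

    record: PatientRecord
    met: frozenset[str]
    not_applicable: frozenset[str]
    group_a: bool
    group_b: bool
    group_c: bool
    life_threatening: bool
    events: tuple[str, ...] = field(default=())
    incomplete: bool = False
    assessable: bool = True


def classify_record(record: PatientRecord, config: ToolConfig | None = None) -> ClassificationResult:
    """Classify one record against all sixteen WHO MNM criteria.

    Pure: identical (record, config) always yields an identical result.
    """
    if config is None:
        config = ToolConfig()

    met: list[str] = []
    not_applicable: list[str] = []
    for crit in CATALOG:
        outcome = evaluate_criterion(record, crit.id, config)
        if outcome is NA:
            not_applicable.append(crit.id)
        elif outcome:
            met.append(crit.id)

    met_set = frozenset(met)
    group_a = any(i.startswith("A") for i in met_set)
    group_b = any(i.startswith("B") for i in met_set)
    group_c = any(i.startswith("C") for i in met_set)
    life_threatening = group_c or (
        config.any_transfusion_low_resource
        and record.setting is Setting.low_resource
        and record.units_blood is not None
        and record.units_blood >= 1
    )

    missing = (
        record.group_a_all_missing(),
        record.group_b_all_missing(),
        record.group_c_all_missing(),
    )
    return ClassificationResult(
        record=record,
        met=met_set,
        not_applicable=frozenset(not_applicable),
        group_a=group_a,
        group_b=group_b,
        group_c=group_c,
        life_threatening=life_threatening,
        events=tuple(met),  # catalog order, no duplicates
        incomplete=any(missing),
        assessable=not all(missing),
    )


def classify_cohort(
    records: list[PatientRecord], config: ToolConfig | None = None
) -> list[ClassificationResult]:
    """Classify every record; order is preserved."""
    cfg = config if config is not None else ToolConfig()
    return [classify_record(r, cfg) for r in records]
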