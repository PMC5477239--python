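"""Cohort-level aggregation and between-cohort comparison.

Turns per-woman :class:`~nearmiss.classify.ClassificationResult` lists into
the outputs used to compare severe maternal outcome (SMO) across settings:
detection rates per criteria group, event tables with event-total
denominators, banded characteristics tables, case fatality rates (CFR), the
corrected ("any transfusion in low-resource settings is life-threatening")
analysis, and chi-square / t-test comparisons with the significance flags
``a`` (p < 0.05) and ``b`` (p < 0.0001).

Percentages are rounded half-away-from-zero to one decimal (integer for
proportions of deaths), the convention that reproduces every published
aggregate this package re-derives.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CATALOG, GROUPS
from .classify import ClassificationResult
from .records import ToolConfig

__all__ = [
    "round1",
    "round0",
    "pct",
    "BandedCounts",
    "CohortSummary",
    "ComparisonResult",
    "significance_flag",
    "summarize_cohort",
    "pooled_counts",
    "pooled_detection",
    "life_threatening_population",
    "detection_delta",
    "case_fatality_rate",
    "deaths_without_organ_dysfunction",
    "event_table",
    "format_event_table",
    "compare_categorical",
    "compare_numeric",
    "AGE_BANDS",
    "PARITY_BANDS",
    "UNITS_BANDS",
]

AGE_BANDS: tuple[str, ...] = ("<20", "20-35", ">35")
PARITY_BANDS: tuple[str, ...] = ("0", "1", ">=2")
UNITS_BANDS: tuple[str, ...] = ("0", "1", "2", "3", "4", ">=5")


def round1(value: float) -> float:
    """Round to 1 decimal, ties away from zero (printed-table convention)."""
    return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round0(value: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(Decimal(str(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def pct(count: float, n: float) -> float:
    """Percentage ``100*count/n`` rounded with :func:`round1`."""
    if n <= 0:
        raise ValueError("percentage denominator must be positive")
    return round1(100.0 * count / n)


def age_band(age: float) -> str:
    if age < 20:
        return "<20"
    if age <= 35:
        return "20-35"
    return ">35"


def parity_band(parity: int) -> str:
    if parity >= 2:
        return ">=2"
    return str(parity)


def units_band(units: int) -> str:
    if units >= 5:
        return ">=5"
    return str(units)


@dataclass(frozen=True)
class BandedCounts:
    """Counts of one banded characteristic, with its "data available" n."""

    bands: tuple[str, ...]
    counts: dict[str, int]
    n_available: int

    def percents(self) -> dict[str, float]:
        if self.n_available == 0:
            return {b: float("nan") for b in self.bands}
        return {b: pct(self.counts[b], self.n_available) for b in self.bands}


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate WHO-MNM classification results for one cohort.

    ``n_women`` counts assessable records only; records with no marker
    recorded in any of the three criteria groups are excluded from every
    denominator and tallied in ``n_excluded``. Event counts are ``None``
    for criteria not applicable in the cohort.
    """

    cohort_id: str
    n_women: int
    n_excluded: int
    group_counts: dict[str, int]          # women with >=1 met criterion, per group
    group_percents: dict[str, float]
    event_counts: dict[str, Optional[int]]  # per criterion id; None = N/A
    group_event_totals: dict[str, int]
    age_bands: BandedCounts
    parity_bands: BandedCounts
    units_bands: BandedCounts
    deaths: int
    cfr_percent: float
    life_threatening_count: int
    life_threatening_percent: float


def summarize_cohort(
    results: Sequence[ClassificationResult], config: ToolConfig | None = None
) -> CohortSummary:
    """Aggregate one cohort's classification results.

    All records must share a ``cohort_id``. Raises ``ValueError`` on an empty
    cohort or on mixed cohorts.
    """
    if config is None:
        config = ToolConfig()
    if not results:
        raise ValueError("cannot summarize an empty cohort")
    cohort_ids = {r.record.cohort_id for r in results}
    if len(cohort_ids) != 1:
        raise ValueError(f"records from multiple cohorts: {sorted(cohort_ids)}")
    (cohort_id,) = cohort_ids

    assessable = [r for r in results if r.assessable]
    n_excluded = len(results) - len(assessable)
    if not assessable:
        raise ValueError(f"cohort {cohort_id!r} has no assessable records")
    n = len(assessable)

    group_counts = {
        "A": sum(r.group_a for r in assessable),
        "B": sum(r.group_b for r in assessable),
        "C": sum(r.group_c for r in assessable),
    }
    group_percents = {g: pct(c, n) for g, c in group_counts.items()}

    na_ids = frozenset().union(*(r.not_applicable for r in assessable)) if assessable else frozenset()
    event_counts: dict[str, Optional[int]] = {}
    for crit in CATALOG:
        if crit.id in na_ids:
            event_counts[crit.id] = None
        else:
            event_counts[crit.id] = sum(crit.id in r.met for r in assessable)
    group_event_totals = {
        g: sum(c for crit, c in event_counts.items() if crit.startswith(g) and c is not None)
        for g in GROUPS
    }

    def banded(values, bands, to_band):
        present = [v for v in values if v is not None]
        counts = {b: 0 for b in bands}
        for v in present:
            counts[to_band(v)] += 1
        return BandedCounts(bands=bands, counts=counts, n_available=len(present))

    records = [r.record for r in assessable]
    ages = banded([r.age_years for r in records], AGE_BANDS, age_band)
    parities = banded([r.parity for r in records], PARITY_BANDS, parity_band)
    units = banded([r.units_blood for r in records], UNITS_BANDS, units_band)

    deaths = sum(r.record.died for r in assessable)
    lt = sum(r.life_threatening for r in assessable)
    return CohortSummary(
        cohort_id=cohort_id,
        n_women=n,
        n_excluded=n_excluded,
        group_counts=group_counts,
        group_percents=group_percents,
        event_counts=event_counts,
        group_event_totals=group_event_totals,
        age_bands=ages,
        parity_bands=parities,
        units_bands=units,
        deaths=deaths,
        cfr_percent=pct(deaths, n),
        life_threatening_count=lt,
        life_threatening_percent=pct(lt, n),
    )


def pooled_counts(pairs: Sequence[tuple[int, int]]) -> tuple[int, int, float]:
    """Pool (count, n) pairs: (sum of counts, sum of n, rounded percent)."""
    if not pairs:
        raise ValueError("nothing to pool")
    count = sum(c for c, _ in pairs)
    n = sum(m for _, m in pairs)
    return count, n, pct(count, n)


def pooled_detection(summaries: Sequence[CohortSummary], group: str) -> tuple[int, int, float]:
    """Pooled detection count, denominator and percent for one criteria group."""
    if group not in GROUPS:
        raise ValueError(f"unknown criteria group {group!r}")
    return pooled_counts([(s.group_counts[group], s.n_women) for s in summaries])


def life_threatening_population(
    results: Sequence[ClassificationResult], config: ToolConfig | None = None
) -> tuple[list[ClassificationResult], CohortSummary]:
    """The life-threatening subset of a cohort and its summary.

    The subset is defined by the ``life_threatening`` flag the records were
    classified with; corrected vs uncorrected analyses differ purely by the
    ``any_transfusion_low_resource`` setting used at classification time.
    """
    subset = [r for r in results if r.assessable and r.life_threatening]
    if not subset:
        raise ValueError("life-threatening subset is empty")
    return subset, summarize_cohort(subset, config)


def detection_delta(uncorrected_percent: float, corrected_percent: float) -> float:
    """Change in detection rate, in percentage points (1 decimal)."""
    for p in (uncorrected_percent, corrected_percent):
        if not 0.0 <= p <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    return round1(corrected_percent - uncorrected_percent)


def case_fatality_rate(deaths: int, n: int) -> float:
    """CFR as a rounded percentage of the population at risk."""
    if n <= 0:
        raise ValueError("population size must be positive")
    if not 0 <= deaths <= n:
        raise ValueError("deaths must lie between 0 and n")
    return pct(deaths, n)


def deaths_without_organ_dysfunction(
    results: Sequence[ClassificationResult],
) -> tuple[int, Optional[int]]:
    """Maternal deaths the organ-dysfunction criteria fail to capture.

    Returns (count, percent-of-deaths rounded to integer). With zero deaths
    the count is 0 and the percent is ``None``.
    """
    deaths = [r for r in results if r.assessable and r.record.died]
    missed = sum(not r.group_c for r in deaths)
    if not deaths:
        return 0, None
    return missed, round0(100.0 * missed / len(deaths))


def event_table(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Subcategory × cohort event matrix.

    Rows are (group, criterion id, label); one column of event counts per
    cohort, with ``pd.NA`` marking criteria not applicable there. The
    per-(group, cohort) event-total denominators — the published tables'
    column N — are stored in ``df.attrs["denominators"]``.
    """
    if not summaries:
        raise ValueError("need at least one cohort")
    index = pd.MultiIndex.from_tuples(
        [(c.group, c.id, c.label) for c in CATALOG], names=["group", "criterion", "label"]
    )
    data = {}
    for s in summaries:
        data[s.cohort_id] = [
            pd.NA if s.event_counts[c.id] is None else s.event_counts[c.id] for c in CATALOG
        ]
    df = pd.DataFrame(data, index=index, dtype="Int64")
    df.attrs["denominators"] = {
        (g, s.cohort_id): s.group_event_totals[g] for s in summaries for g in GROUPS
    }
    return df


def format_event_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render an event table as "count (percent)" strings, "N/A" where absent.

    Percentages use the cohort's group event total as denominator, mirroring
    the published presentation.
    """
    denoms = table.attrs["denominators"]
    out = {}
    for cohort in table.columns:
        col = []
        for (group, _, _), value in zip(table.index, table[cohort]):
            if value is pd.NA or pd.isna(value):
                col.append("N/A")
            else:
                denom = denoms[(group, cohort)]
                col.append(f"{int(value)} ({pct(int(value), denom)})" if denom else f"{int(value)}")
        out[cohort] = col
    return pd.DataFrame(out, index=table.index)


@dataclass(frozen=True)
class ComparisonResult:
    """A between-cohort test with the published significance flags."""

    table: Optional[pd.DataFrame]
    statistic: float
    dof: int
    p_value: float
    flag: str  # "ns", "a" (p<0.05) or "b" (p<0.0001)


def significance_flag(p_value: float) -> str:
    if p_value < 1e-4:
        return "b"
    if p_value < 0.05:
        return "a"
    return "ns"


def compare_categorical(table: pd.DataFrame | np.ndarray) -> ComparisonResult:
    """Pearson chi-square test of homogeneity on a category × cohort table.

    No continuity correction, no exact test. Raises ``ValueError`` for
    tables smaller than 2×2, negative or non-integer entries, or a zero
    row/column marginal (naming the offending category).
    """
    df = pd.DataFrame(table)
    arr = df.to_numpy()
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table entries must be counts")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for label, total in zip(df.index, row_sums):
        if total == 0:
            raise ValueError(f"zero marginal for category {label!r}")
    for label, total in zip(df.columns, col_sums):
        if total == 0:
            raise ValueError(f"zero marginal for cohort {label!r}")
    res = stats.chi2_contingency(arr, correction=False)
    return ComparisonResult(
        table=df,
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        flag=significance_flag(float(res.pvalue)),
    )


def compare_numeric(sample_a: Sequence[float], sample_b: Sequence[float]) -> ComparisonResult:
    """Two-sided independent-samples t-test (pooled variance)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            # identical constant samples: no evidence of a difference
            return ComparisonResult(table=None, statistic=0.0, dof=int(a.size + b.size - 2), p_value=1.0, flag="ns")
        raise ValueError("both samples have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        table=None,
        statistic=float(res.statistic),
        dof=int(a.size + b.size - 2),
        p_value=float(res.pvalue),
        flag=significance_flag(float(res.pvalue)),
    )
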