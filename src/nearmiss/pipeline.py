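"""End-to-end analysis pipeline: cohorts in, comparison tables out.

Mirrors the published analysis sequence: local SMO inclusion → WHO MNM
classification → per-cohort summaries → pooled detection → corrected
life-threatening analysis → between-cohort chi-square comparisons. Each
stage logs its record counts; any stage failure aborts the run with a
stage-named error and removes partial outputs.

Configuration is a small YAML/dict hierarchy mirroring
:class:`~nearmiss.records.ToolConfig` plus cohort sources::

    cohorts:
      - preset: NL          # or  csv: path/to/records.csv
      - preset: TZ
      - preset: MW
    tool:
      massive_transfusion_threshold: 5
      any_transfusion_low_resource: false
    seed: 1
    output_dir: out/

Defaults reproduce the uncorrected analysis; toggling
``any_transfusion_low_resource`` changes only the life-threatening tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import published
from .analysis import (
    CohortSummary,
    compare_categorical,
    deaths_without_organ_dysfunction,
    detection_delta,
    event_table,
    format_event_table,
    life_threatening_population,
    pct,
    pooled_counts,
    pooled_detection,
    summarize_cohort,
)
from .classify import ClassificationResult, classify_cohort
from .io import read_patient_table
from .records import PatientRecord, ToolConfig
from .simulate import generate_cohort, preset_specs

__all__ = ["PipelineError", "run_pipeline", "to_markdown"]

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A pipeline stage failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def to_markdown(frame: pd.DataFrame) -> str:
    """Minimal GitHub-style pipe table (no external table dependency)."""
    df = frame
    if df.index.name is not None or df.index.nlevels > 1 or not df.index.equals(
        pd.RangeIndex(len(df))
    ):
        df = df.reset_index()
    header = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |", "| " + " | ".join("---" for _ in header) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines) + "\n"


def _tool_config(raw: dict) -> ToolConfig:
    tool = dict(raw.get("tool") or {})
    tool.setdefault("available_interventions", dict(published.AVAILABLE_INTERVENTIONS))
    tool["available_interventions"] = {
        k: frozenset(v) for k, v in tool["available_interventions"].items()
    }
    return ToolConfig(**tool)


def _load_cohorts(raw: dict, seed: int) -> dict[str, list[PatientRecord]]:
    sources = raw.get("cohorts")
    if not sources:
        raise PipelineError("load", "config lists no cohorts")
    presets = preset_specs()
    cohorts: dict[str, list[PatientRecord]] = {}
    for offset, source in enumerate(sources):
        if "preset" in source:
            name = source["preset"]
            if name not in presets:
                raise PipelineError("load", f"unknown preset {name!r}")
            spec = presets[name]
            if "n_women" in source:
                spec = spec.model_copy(update={"n_women": int(source["n_women"])})
            records = generate_cohort(spec, seed + offset)
        elif "csv" in source:
            records = read_patient_table(source["csv"])
        else:
            raise PipelineError("load", f"cohort source needs 'preset' or 'csv': {source}")
        if not records:
            raise PipelineError("load", f"cohort source {source} produced no records")
        (cohort_id,) = {r.cohort_id for r in records}
        cohorts[cohort_id] = records
        logger.info("stage load: cohort %s, %d records", cohort_id, len(records))
    return cohorts


def _detection_table(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    rows = []
    for group, label in (("A", "disease-based"), ("B", "intervention-based"), ("C", "organ-dysfunction-based")):
        row: dict[str, object] = {"criteria_group": label}
        for s in summaries:
            row[s.cohort_id] = f"{s.group_counts[group]} ({s.group_percents[group]})"
        count, n, percent = pooled_detection(summaries, group)
        row["pooled"] = f"{count} ({percent})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("criteria_group")


def _characteristics_table(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    rows = []
    for var, attr in (("age", "age_bands"), ("parity", "parity_bands"), ("units_blood", "units_bands")):
        avail = {"variable": var, "band": "data available"}
        for s in summaries:
            avail[s.cohort_id] = getattr(s, attr).n_available
        rows.append(avail)
        bands = getattr(summaries[0], attr).bands
        for band in bands:
            row = {"variable": var, "band": band}
            for s in summaries:
                bc = getattr(s, attr)
                row[s.cohort_id] = (
                    f"{bc.counts[band]} ({pct(bc.counts[band], bc.n_available)})"
                    if bc.n_available
                    else "0"
                )
            rows.append(row)
    return pd.DataFrame(rows).set_index(["variable", "band"])


def _cfr_table(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "cohort": s.cohort_id,
                "n": s.n_women,
                "deaths": s.deaths,
                "cfr_percent": s.cfr_percent,
            }
        )
    count, n, percent = pooled_counts([(s.deaths, s.n_women) for s in summaries])
    rows.append({"cohort": "pooled", "n": n, "deaths": count, "cfr_percent": percent})
    return pd.DataFrame(rows).set_index("cohort")


def _comparison_rows(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Chi-square per banded characteristic and per event subcategory.

    Event rows compare one subcategory against the rest of its group's
    events; rows with a not-applicable cell in any cohort are dropped,
    as are rows with a zero marginal.
    """
    rows = []
    for var, attr in (("age", "age_bands"), ("parity", "parity_bands"), ("units_blood", "units_bands")):
        table = pd.DataFrame(
            {s.cohort_id: [getattr(s, attr).counts[b] for b in getattr(s, attr).bands] for s in summaries},
            index=list(getattr(summaries[0], attr).bands),
        )
        try:
            res = compare_categorical(table)
        except ValueError as exc:
            logger.info("skipping chi-square for %s: %s", var, exc)
            continue
        rows.append(
            {"comparison": var, "chi2": res.statistic, "dof": res.dof, "p_value": res.p_value, "flag": res.flag}
        )
    events = event_table(list(summaries))
    n_women = {s.cohort_id: s.n_women for s in summaries}
    for (group, cid, label), counts in events.iterrows():
        if counts.isna().any():
            continue
        # women with vs without the event, per cohort (one event per woman,
        # so the event count is a women count)
        table = pd.DataFrame(
            {
                s.cohort_id: [
                    int(counts[s.cohort_id]),
                    n_women[s.cohort_id] - int(counts[s.cohort_id]),
                ]
                for s in summaries
            },
            index=[cid, f"no {cid}"],
        )
        try:
            res = compare_categorical(table)
        except ValueError as exc:
            logger.info("skipping chi-square for %s: %s", cid, exc)
            continue
        rows.append(
            {"comparison": f"{cid} {label}", "chi2": res.statistic, "dof": res.dof, "p_value": res.p_value, "flag": res.flag}
        )
    if not rows:  # single-cohort runs have nothing to compare
        return pd.DataFrame(columns=["chi2", "dof", "p_value", "flag"]).rename_axis("comparison")
    return pd.DataFrame(rows).set_index("comparison")


def _life_threatening_table(
    classified: dict[str, list[ClassificationResult]],
    corrected: dict[str, list[ClassificationResult]],
) -> pd.DataFrame:
    rows = []
    un_pairs, co_pairs = [], []
    for cohort, results in classified.items():
        n = sum(r.assessable for r in results)
        un = sum(r.assessable and r.life_threatening for r in results)
        co = sum(r.assessable and r.life_threatening for r in corrected[cohort])
        un_pairs.append((un, n))
        co_pairs.append((co, n))
        rows.append(
            {
                "cohort": cohort,
                "n": n,
                "uncorrected": f"{un} ({pct(un, n)})",
                "corrected": f"{co} ({pct(co, n)})",
            }
        )
    un_c, n_tot, un_p = pooled_counts(un_pairs)
    co_c, _, co_p = pooled_counts(co_pairs)
    rows.append(
        {
            "cohort": "pooled",
            "n": n_tot,
            "uncorrected": f"{un_c} ({un_p})",
            "corrected": f"{co_c} ({co_p})",
        }
    )
    df = pd.DataFrame(rows).set_index("cohort")
    df.attrs["detection_increase_points"] = detection_delta(un_p, co_p)
    return df


def _provenance(raw: dict, seed: int) -> dict[str, object]:
    try:
        tool_version = version("nearmiss")
    except PackageNotFoundError:  # pragma: no cover
        tool_version = "unknown"
    digest = hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {"tool": f"nearmiss {tool_version}", "seed": seed, "config_sha256": digest}


def run_pipeline(config: dict | str | Path) -> dict[str, pd.DataFrame]:
    """Run the full comparison pipeline and write its report bundle.

    ``config`` is a mapping or a path to a YAML file (see module docstring).
    Returns the report tables; writes each as CSV and markdown under
    ``output_dir`` when set. On any stage error, partially written outputs
    are removed and :class:`PipelineError` is raised.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(config)
    seed = int(raw.get("seed", 0))
    tool = _tool_config(raw)
    corrected_tool = tool.model_copy(update={"any_transfusion_low_resource": True})
    uncorrected_tool = tool.model_copy(update={"any_transfusion_low_resource": False})

    cohorts = _load_cohorts(raw, seed)

    classified: dict[str, list[ClassificationResult]] = {}
    corrected: dict[str, list[ClassificationResult]] = {}
    for cohort_id, records in cohorts.items():
        classified[cohort_id] = classify_cohort(records, uncorrected_tool)
        corrected[cohort_id] = classify_cohort(records, corrected_tool)
        excluded = sum(not r.assessable for r in classified[cohort_id])
        logger.info(
            "stage classify: cohort %s, %d records, %d excluded (insufficient data)",
            cohort_id,
            len(records),
            excluded,
        )

    # detection/event/characteristics tables do not depend on the correction
    # flag; only the life-threatening accounting does, so the configured flag
    # selects which classification feeds the summaries
    primary = corrected if tool.any_transfusion_low_resource else classified
    try:
        summaries = [summarize_cohort(res, tool) for res in primary.values()]
    except ValueError as exc:
        raise PipelineError("summarize", str(exc)) from exc

    tables: dict[str, pd.DataFrame] = {}
    try:
        tables["detection"] = _detection_table(summaries)
        tables["events"] = format_event_table(event_table(summaries))
        tables["characteristics"] = _characteristics_table(summaries)
        tables["cfr"] = _cfr_table(summaries)
        tables["life_threatening"] = _life_threatening_table(classified, corrected)
        tables["comparisons"] = _comparison_rows(summaries)
        dwod_rows = []
        for cohort_id, results in classified.items():
            count, percent = deaths_without_organ_dysfunction(results)
            dwod_rows.append(
                {"cohort": cohort_id, "missed_deaths": count,
                 "percent_of_deaths": "" if percent is None else percent}
            )
        tables["deaths_without_organ_dysfunction"] = pd.DataFrame(dwod_rows).set_index("cohort")
        for name, results in classified.items():
            if any(r.life_threatening for r in results if r.assessable):
                _, lt_summary = life_threatening_population(results, uncorrected_tool)
                logger.info(
                    "stage life-threatening: cohort %s, %d women, CFR %.1f%%",
                    name,
                    lt_summary.n_women,
                    lt_summary.cfr_percent,
                )
    except (ValueError, KeyError) as exc:
        raise PipelineError("report", str(exc)) from exc

    out_dir = raw.get("output_dir")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        prov = _provenance(raw, seed)
        header = "".join(f"# {k}: {v}\n" for k, v in prov.items())
        try:
            for name, table in tables.items():
                csv_path = out / f"{name}.csv"
                with csv_path.open("w", encoding="utf-8") as fh:
                    fh.write(header)
                    table.to_csv(fh)
                written.append(csv_path)
                md_path = out / f"{name}.md"
                md_path.write_text(to_markdown(table.reset_index()), encoding="utf-8")
                written.append(md_path)
        except OSError as exc:
            for path in written:
                path.unlink(missing_ok=True)
            raise PipelineError("write", str(exc)) from exc
        logger.info("stage write: %d files in %s", len(written), out)
    return tables
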