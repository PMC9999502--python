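"""End-to-end orchestration: inputs -> resolved criteria -> screen -> tables.

The pipeline is deliberately file-oriented: every stage reads and writes
headered CSV so intermediate products can be inspected, and the rendered
Markdown report is generated from the output CSVs alone (never recomputed),
keeping every reported number traceable to a CSV cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import synthetic_criteria
from .criteria import (
    Criterion,
    CriterionSet,
    FormularyEntry,
    group_statements,
    load_formulary_csv,
    load_statements_csv,
    pre_screen_summary,
    resolve_all,
)
from .register import (
    DEFAULT_FORM_BLOCKLIST,
    build_cohorts,
    load_census,
    load_register,
)
from .screening import ScreenResult, pims_per_person_distribution, screen
from .stats import (
    overlap_table,
    prevalence_table,
    sensitivity_prevalence,
    top_n,
    usage_by_group,
)

logger = logging.getLogger(__name__)


class PipelineInputError(Exception):
    """A required input path is missing or unreadable (exit code 2)."""


class PipelineValidationError(Exception):
    """Inputs were read but fail validation (exit code 3)."""


@dataclass
class RunConfig:
    register: str
    census: str
    outdir: str
    criteria: str | None = None      # None -> packaged synthetic reference
    formulary: str | None = None
    age_floor: int = 75
    form_blocklist: Sequence[str] = DEFAULT_FORM_BLOCKLIST
    reference_criterion: str = "meds75"
    group_level: int = 4
    top_n: int = 3
    sensitivity: Sequence[Mapping] = field(default_factory=tuple)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise PipelineInputError(f"cannot read run config {path}: {exc}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineValidationError(f"invalid run config: {exc}")


def load_criteria_inputs(
    criteria_path: str | None, formulary_path: str | None
) -> tuple[list[Criterion], list[FormularyEntry]]:
    """Load criteria/formulary CSVs, or the packaged synthetic reference."""
    if criteria_path is None and formulary_path is None:
        crits, form = synthetic_criteria.reference_criteria()
        return list(crits), list(form)
    if criteria_path is None or formulary_path is None:
        raise PipelineValidationError(
            "criteria and formulary must be given together"
        )
    for p in (criteria_path, formulary_path):
        if not Path(p).is_file():
            raise PipelineInputError(f"input file not found: {p}")
    try:
        statements = load_statements_csv(criteria_path)
        formulary = load_formulary_csv(formulary_path)
    except (ValueError, KeyError) as exc:
        raise PipelineValidationError(f"invalid criteria inputs: {exc}")
    return group_statements(statements, synthetic_criteria.CRITERIA_META), formulary


def screen_result_from_long(df: pd.DataFrame, criterion_id: str) -> ScreenResult:
    """Rebuild a ScreenResult from its long-format exposure CSV rows."""
    sub = df[df["criterion_id"] == criterion_id]
    users_by_year = {
        int(y): frozenset(g["person_id"]) for y, g in sub.groupby("year")
    }
    per_person = {
        p: frozenset(g["atc_code"]) for p, g in sub.groupby("person_id")
    }
    per_code = {
        c: frozenset(g["person_id"]) for c, g in sub.groupby("atc_code")
    }
    result = ScreenResult(
        criterion_id=criterion_id,
        users_by_year=users_by_year,
        per_person_codes=per_person,
        per_code_users=per_code,
    )
    result._codes_in_year = {
        (int(y), p): frozenset(g["atc_code"])
        for (y, p), g in sub.groupby(["year", "person_id"])
    }
    return result


def compute_tables(
    results: Mapping[str, ScreenResult],
    census: Mapping[int, float],
    reference_criterion: str,
    group_level: int,
    n_top: int,
) -> dict[str, pd.DataFrame]:
    """All published-style statistics tables from screen results."""
    pooled_all = frozenset().union(
        *(r.pooled_users for r in results.values())
    )
    denominator = len(pooled_all)
    tables = {
        "prevalence": prevalence_table(results, census),
        "overlap": overlap_table(results, reference_criterion),
        "pims_per_person": pd.DataFrame(
            [
                {"criterion_id": cid, **pims_per_person_distribution(res)}
                for cid, res in results.items()
            ]
        ),
    }
    if denominator > 0:
        tables["class_usage"] = usage_by_group(results, group_level, denominator)
        tables["top_pims"] = pd.concat(
            [top_n(res, denominator, n_top) for res in results.values()],
            ignore_index=True,
        )
    else:
        tables["class_usage"] = pd.DataFrame(
            columns=["group", "criterion_id", "users", "proportion_pct"]
        )
        tables["top_pims"] = pd.DataFrame(
            columns=["criterion_id", "rank", "atc_code", "users", "proportion_pct"]
        )
    return tables


def render_report(outdir: Path) -> str:
    """Render a Markdown report purely from the pipeline's output CSVs."""
    lines = ["# PIM screening report", ""]
    for name, title in [
        ("prevalence", "Annual prevalence of PIM use (%)"),
        ("overlap", "Overlap of PIM users with the reference criterion (%)"),
        ("pims_per_person", "Distinct PIMs per PIM user"),
        ("class_usage", "Users of ATC classes among all PIM users (%)"),
        ("top_pims", "Most-used PIMs per criterion (%)"),
        ("sensitivity", "Sensitivity analyses: prevalence with exclusions (%)"),
    ]:
        path = outdir / f"{name}.csv"
        if not path.is_file():
            continue
        df = pd.read_csv(path)
        lines.append(f"## {title}\n")
        lines.append(df.to_markdown(index=False))
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full screening analysis; return paths of all outputs."""
    for p in (config.register, config.census):
        if not Path(p).is_file():
            raise PipelineInputError(f"input file not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    criteria, formulary = load_criteria_inputs(config.criteria, config.formulary)
    criterion_sets = resolve_all(criteria, formulary)
    universe = frozenset().union(
        *(cs.resolved_codes for cs in criterion_sets.values())
    )

    records, load_rejects = load_register(config.register, config.form_blocklist)
    census = load_census(config.census)
    try:
        cohorts, cohort_rejects = build_cohorts(
            records, census, universe, config.age_floor, config.form_blocklist
        )
    except KeyError as exc:
        raise PipelineValidationError(str(exc))

    results = {
        cid: screen(cohorts, cs) for cid, cs in criterion_sets.items()
    }
    tables = compute_tables(
        results, census, config.reference_criterion,
        config.group_level, config.top_n,
    )

    sens_frames = []
    for spec in config.sensitivity:
        cid = spec["criterion"]
        frame = sensitivity_prevalence(
            cohorts,
            criterion_sets[cid],
            census,
            excluded=spec.get("exclude", ()),
            keep_exceptions=spec.get("keep", ()),
        )
        frame.insert(0, "analysis", spec.get("name", cid))
        sens_frames.append(frame)
    if sens_frames:
        tables["sensitivity"] = pd.concat(sens_frames, ignore_index=True)

    exposure = pd.concat(
        [res.to_long_frame() for res in results.values()], ignore_index=True
    )
    rejections = pd.concat([load_rejects, cohort_rejects], ignore_index=True)

    paths: dict[str, Path] = {}
    for name, df in {**tables, "exposure": exposure, "rejections": rejections}.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    provenance = {
        "criteria_source": config.criteria or "packaged synthetic reference",
        "n_criteria": len(criteria),
        "pre_screen_codes": len(pre_screen_summary(criteria)),
        "post_screen_codes": len(universe),
        "register_rows": int(len(records) + len(load_rejects)),
        "retained_rows": int(sum(len(c.records) for c in cohorts.values())),
        "rejected_rows": int(len(rejections)),
        "age_floor": config.age_floor,
        "years": sorted(int(y) for y in cohorts),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    paths["provenance"] = prov_path

    report_path = outdir / "report.md"
    report_path.write_text(render_report(outdir))
    paths["report"] = report_path
    return paths
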