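"""Pipeline orchestration and table rendering.

:func:`run_pipeline` drives ingest -> filter -> dedup -> normalize ->
tables -> disproportionality panel from a single YAML config and writes
delimited-text tables plus a JSON run manifest capturing every setting and
per-stage record count, so a run can be reproduced byte-identically.

:func:`render_table` turns result collections into delimited text with the
conventional layouts: counts as integers, percentages to 1 decimal, ROR and
CI bounds to 2 decimals, p-values to 6 decimals ("1.0" for a unit p, "N.A."
where no test applies).
"""

from __future__ import annotations

import csv
import io
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .descriptive import (
    DeathSummary,
    StratifiedReactionTable,
    age_distribution,
    death_summary,
    reaction_frequency,
    round_half_up,
    sex_distribution,
)
from .disproportionality import DisproportionalityResult, Z_95, compare_drug_panel
from .icsr import (
    CohortCriteria,
    ICSRecord,
    MedDRAMap,
    Region,
    Sex,
    read_line_listing,
)
from .processing import (
    apply_cohort_criteria,
    drop_duplicates,
    drop_incomplete,
    find_duplicates,
    normalize_reactions,
)

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "render_table", "format_p"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def format_p(p: float | None) -> str:
    """p to 6 decimals; unit p as '1.0'; no test as 'N.A.'."""
    if p is None:
        return "N.A."
    if p >= 1.0:
        return "1.0"
    return f"{p:.6f}"


def _fmt_ror(r: DisproportionalityResult) -> tuple[str, str]:
    lo, hi = r.ci_display
    return f"{r.ror_display:.2f}", f"{lo:.2f}-{hi:.2f}"


def render_table(
    results: Sequence[Any],
    style: str,
    cohort_label: str = "",
) -> str:
    """Render a result collection as CSV text for the given style.

    Styles: ``frequency`` (term/count/% of all reports), ``sex`` and ``age``
    (stratified counts, row percentages and the test p), ``death`` (the
    fatal-outcome summary), ``panel`` (cases/non-cases per drug with ROR and
    CI), ``soc`` ((SOC, count) pairs).
    """
    buf = io.StringIO()
    writer = csv.writer(buf)
    if style == "frequency":
        writer.writerow(["reaction", "cases", "pct_of_all"])
        for term, count, pct in results:
            writer.writerow([term, count, f"{pct:.1f}"])
    elif style in ("sex", "age"):
        s1, s2 = ("male", "female") if style == "sex" else ("stratum1", "stratum2")
        writer.writerow(
            ["reaction", s1, f"{s1}_pct", s2, f"{s2}_pct", "total", "pct_of_all", "p_value"]
        )
        for row in results:
            if not isinstance(row, StratifiedReactionTable):
                raise ValueError(f"style {style!r} needs stratified rows, got {type(row)!r}")
            writer.writerow(
                [
                    row.term,
                    row.count_stratum1,
                    f"{round_half_up(row.pct_stratum1, 1):.1f}",
                    row.count_stratum2,
                    f"{round_half_up(row.pct_stratum2, 1):.1f}",
                    row.row_total,
                    f"{row.pct_of_all:.1f}",
                    format_p(row.p_value),
                ]
            )
    elif style == "death":
        (summary,) = results
        if not isinstance(summary, DeathSummary):
            raise ValueError("death style needs a DeathSummary")
        writer.writerow(["stratum", "deaths", "pct"])
        writer.writerow(["all", summary.total, f"{summary.pct_total:.1f}"])
        for group, (deaths, _n) in summary.by_age.items():
            writer.writerow([group.value, deaths, f"{summary.pct_age(group):.1f}"])
        for sex in (Sex.MALE, Sex.FEMALE):
            if sex in summary.by_sex:
                writer.writerow(
                    [sex.value.lower(), summary.by_sex[sex], f"{summary.pct_sex(sex):.1f}"]
                )
    elif style == "panel":
        writer.writerow(
            [
                "event",
                "drug_a",
                "cases_a",
                "noncases_a",
                "drug_b",
                "cases_b",
                "noncases_b",
                "ror",
                "ci95",
                "signal",
            ]
        )
        for r in results:
            if not isinstance(r, DisproportionalityResult):
                raise ValueError(f"panel style needs DisproportionalityResult, got {type(r)!r}")
            ror, ci = _fmt_ror(r)
            writer.writerow(
                [
                    r.event_label,
                    r.drug_a,
                    r.table.a,
                    r.table.b,
                    r.drug_b,
                    r.table.c,
                    r.table.d,
                    ror,
                    ci,
                    "yes" if r.signal else "no",
                ]
            )
    elif style == "soc":
        writer.writerow(["soc", "cases"])
        for soc, count in results:
            writer.writerow([soc, count])
    else:
        raise ValueError(f"unknown table style {style!r}")
    return buf.getvalue()


@dataclass
class RunManifest:
    """Everything needed to re-execute a pipeline run."""

    version: str
    seed: int | None
    inputs: dict[str, str]
    criteria: dict[str, Any]
    dedup: dict[str, Any]
    statistics: dict[str, Any]
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _parse_criteria(raw: dict[str, Any], drug: str | None) -> CohortCriteria:
    regions = raw.get("allowed_regions")
    window = raw.get("date_window")
    return CohortCriteria(
        require_serious=bool(raw.get("require_serious", False)),
        require_hcp_reporter=bool(raw.get("require_hcp_reporter", False)),
        allowed_regions=frozenset(Region(r) for r in regions) if regions else None,
        date_window=tuple(window) if window else None,  # type: ignore[arg-type]
        drug_of_interest=drug,
    )


def _load_cohorts(config: dict[str, Any], base: Path) -> tuple[dict[str, list[ICSRecord]], MedDRAMap]:
    if config.get("use_reference_preset"):
        from .synthetic import reference_study

        study = reference_study()
        return dict(study.raw_records), study.meddra
    inputs = config.get("inputs")
    if not inputs:
        raise PipelineError("ingest: config needs 'inputs' (drug -> listing path) "
                            "or 'use_reference_preset: true'")
    cohorts = {
        drug: read_line_listing(base / path) for drug, path in inputs.items()
    }
    meddra_cfg = config.get("meddra", {})
    if meddra_cfg:
        meddra = MedDRAMap.from_csv(
            base / meddra_cfg["soc_csv"],
            base / meddra_cfg["synonym_csv"] if "synonym_csv" in meddra_cfg else None,
        )
    else:
        meddra = MedDRAMap()
    return cohorts, meddra


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the full pipeline described by a YAML config.

    Returns the output directory, which receives ``frequency.csv``,
    ``sex.csv``, ``age.csv``, ``death.csv``, ``soc.csv``, ``panel.csv`` and
    ``manifest.json``.  Any stage error removes partial outputs and
    re-raises as :class:`PipelineError` naming the stage.
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    base = config_path.parent
    out_dir = Path(config.get("output_dir", base / "pvsignal_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir

    criteria_cfg = config.get("criteria", {})
    dedup_cfg = config.get("dedup", {})
    stats_cfg = config.get("statistics", {})
    jaccard = float(dedup_cfg.get("reaction_threshold", 1.0))
    floored = bool(stats_cfg.get("floored", False))
    z_quantile = float(stats_cfg.get("z_quantile", Z_95))
    correction = stats_cfg.get("zero_cell_correction", "haldane")
    min_count = int(config.get("min_count", 1))

    manifest = RunManifest(
        version=__version__,
        seed=config.get("seed"),
        inputs=dict(config.get("inputs", {})) or {"reference_preset": "builtin"},
        criteria=dict(criteria_cfg),
        dedup={"reaction_threshold": jaccard},
        statistics={
            "floored": floored,
            "z_quantile": z_quantile,
            "zero_cell_correction": correction,
        },
    )
    manifest.notes.append(
        "identical cohort criteria applied to every drug, comparators included"
    )

    try:
        cohorts_raw, meddra = _load_cohorts(config, base)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the stage
        raise PipelineError(f"ingest: {exc}") from exc

    cohorts: dict[str, list[ICSRecord]] = {}
    for drug, raw in cohorts_raw.items():
        counts = {"raw": len(raw)}
        try:
            filtered = apply_cohort_criteria(raw, _parse_criteria(criteria_cfg, drug))
            counts["filtered"] = len(filtered)
            complete = drop_incomplete(filtered)
            counts["complete"] = len(complete)
            deduped = drop_duplicates(complete, find_duplicates(complete, jaccard))
            counts["deduped"] = len(deduped)
            cohorts[drug] = normalize_reactions(deduped, meddra)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"cohort {drug}: {exc}") from exc
        manifest.stage_counts[drug] = counts

    primary = config.get("primary_drug") or next(iter(cohorts))
    if primary not in cohorts:
        raise PipelineError(f"tables: primary drug {primary!r} has no cohort")
    cohort = cohorts[primary]

    outputs: dict[str, str] = {}
    try:
        freq = reaction_frequency(cohort, min_count=min_count)
        outputs["frequency.csv"] = render_table(freq, "frequency")
        terms = [t for t, _c, _p in freq]
        sex_rows = [sex_distribution(cohort, t, floored=floored) for t in terms]
        outputs["sex.csv"] = render_table(sex_rows, "sex")
        age_rows = [age_distribution(cohort, t, floored=floored) for t in terms]
        outputs["age.csv"] = render_table(age_rows, "age")
        outputs["death.csv"] = render_table([death_summary(cohort)], "death")
        from .processing import aggregate_to_soc

        soc_counts = aggregate_to_soc(cohort, meddra)
        outputs["soc.csv"] = render_table(list(soc_counts.items()), "soc")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"tables: {exc}") from exc

    events = config.get("events") or []
    pairs = [tuple(p) for p in config.get("pairs", [])]
    if events and pairs:
        try:
            panel = compare_drug_panel(
                cohorts, events, pairs, meddra=meddra,
                z_quantile=z_quantile, correction=correction,
            )
            outputs["panel.csv"] = render_table(panel, "panel")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"panel: {exc}") from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, text in outputs.items():
            path = out_dir / name
            path.write_text(text, encoding="utf-8")
            written.append(path)
        (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        for path in written:
            path.unlink(missing_ok=True)
        if not any(out_dir.iterdir()):
            shutil.rmtree(out_dir, ignore_errors=True)
        raise PipelineError(f"write: {exc}") from exc
    return out_dir
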