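"""End-to-end orchestration: ingest quarterly files, process cases, run the
four disproportionality algorithms, and write signal tables, the cohort
summary, the onset analysis and a run manifest.

Stage-by-stage record counts (attrition) are first-class outputs in the
manifest: the chain raw reports -> deduplicated cases -> suspect-drug
reports -> drug-event pairs -> filtered pairs -> flagged signals is the only
way to audit a spontaneous-report analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .case_processing import (build_drug_event_pairs, deduplicate,
                              load_two_column_map, map_to_soc,
                              normalize_synonym_table, reports_from_raw,
                              apply_min_count_filter, select_suspect_reports,
                              standardize_drug_rows, suspect_drugs_by_report)
from .cohort_summary import summarize
from .disproportionality import SignalThresholds, build_tables
from .empirical_bayes import GammaMixturePrior
from .faers_io import (RawRecordSet, TABLE_KINDS, quarter_file_name,
                       read_quarter, write_signal_table)
from .onset_time import (compute_onsets, interval_distribution, onset_summary)
from .signal_classification import rank_and_select, score_tables

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels, e.g. 2018Q4 .. 2023Q4."""
    def parse(label: str) -> tuple[int, int]:
        year, q = label.split("Q")
        return int(year), int(q)

    (y0, q0), (y1, q1) = parse(start), parse(end)
    if (y0, q0) > (y1, q1):
        raise ValueError(f"quarter range {start}..{end} is not well-ordered")
    labels = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        labels.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return labels


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    quarter_start: str
    quarter_end: str
    target_drug: str
    synonym_file: str
    pt_soc_file: str
    exclusion_file: str | None = None
    role_policy: str = "PS_only"
    min_pt_count: int = 3
    unmapped_policy: str = "keep_flagged"
    yates: bool = True
    sort_key: str = "ror"
    top_k: int | None = None
    onset_bins: tuple[int, ...] = (7, 30, 60)
    quantile_method: str = "linear"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    prior_init: GammaMixturePrior = field(default_factory=GammaMixturePrior)


def _concat(per_quarter: list[dict[str, RawRecordSet]],
            ) -> dict[str, RawRecordSet]:
    merged = {}
    for kind in TABLE_KINDS:
        first = per_quarter[0][kind]
        rows = [row for q in per_quarter for row in q[kind].rows]
        merged[kind] = RawRecordSet(kind, "all", list(first.columns), rows)
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest.

    Stages run in ingestion order: read quarters -> deduplicate -> suspect
    selection -> PT minimum-count filter -> SOC mapping -> contingency
    tables -> four algorithms -> classification -> cohort summary -> onset
    analysis.  Any stage error aborts with the stage name; the manifest up
    to that point is written to the output directory.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "pvsignal", "version": __version__},
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "counts": {},
        "outputs": [],
    }
    stage = "setup"
    try:
        # ---- ingestion
        stage = "faers_io.read_quarter"
        quarters = quarter_range(config.quarter_start, config.quarter_end)
        in_dir = Path(config.input_dir)
        per_quarter = []
        for label in quarters:
            per_quarter.append(read_quarter(in_dir, label))
            for kind in TABLE_KINDS:
                path = in_dir / quarter_file_name(kind, label)
                manifest["inputs"][path.name] = _sha256(path)
        tables = _concat(per_quarter)
        manifest["counts"]["raw_rows"] = {
            kind: len(tables[kind]) for kind in TABLE_KINDS}

        # ---- case processing
        stage = "case_processing.deduplicate"
        candidates = reports_from_raw(tables["DEMO"], tables["OUTC"])
        reports = deduplicate(candidates)
        keep_ids = {r.primaryid for r in reports}
        manifest["counts"]["candidate_reports"] = len(candidates)
        manifest["counts"]["deduplicated_reports"] = len(reports)

        stage = "case_processing.standardize_drug"
        synonyms = normalize_synonym_table(
            load_two_column_map(config.synonym_file))
        drug_rows = standardize_drug_rows(tables["DRUG"], synonyms)

        stage = "case_processing.select_suspect_reports"
        target_reports = select_suspect_reports(
            reports, drug_rows, config.target_drug, config.role_policy)
        if not target_reports:
            raise PipelineError(
                f"no reports name {config.target_drug!r} as suspect drug")
        manifest["counts"]["target_reports"] = len(target_reports)

        stage = "case_processing.build_drug_event_pairs"
        suspect_by_report = suspect_drugs_by_report(drug_rows,
                                                    config.role_policy)
        pairs = build_drug_event_pairs(tables["REAC"], suspect_by_report,
                                       keep_ids)
        target_pairs = [p for p in pairs if p.drug_id == config.target_drug]
        background_pairs = [p for p in pairs
                            if p.drug_id != config.target_drug]
        manifest["counts"]["target_pairs"] = len(target_pairs)
        manifest["counts"]["background_pairs"] = len(background_pairs)

        stage = "case_processing.apply_min_count_filter"
        target_pairs, dropped = apply_min_count_filter(
            target_pairs, config.min_pt_count)
        manifest["counts"]["target_pairs_after_min_count"] = len(target_pairs)
        manifest["counts"]["pts_dropped_by_min_count"] = len(dropped)

        stage = "case_processing.map_to_soc"
        pt_soc_map = load_two_column_map(config.pt_soc_file)
        all_pairs, soc_log = map_to_soc(target_pairs + background_pairs,
                                        pt_soc_map, config.unmapped_policy)
        manifest["counts"]["soc_mapping"] = dict(soc_log)

        # ---- statistics
        exclusions: list[str] = []
        if config.exclusion_file:
            exclusions = [line.strip() for line in
                          Path(config.exclusion_file).read_text().splitlines()
                          if line.strip()]
        for level in ("PT", "SOC"):
            stage = f"disproportionality.build_tables[{level}]"
            level_tables = build_tables(all_pairs, level, config.target_drug)
            stage = f"signal_classification.score_tables[{level}]"
            results, prior = score_tables(
                level_tables, level, thresholds=config.thresholds,
                yates=config.yates, prior_init=config.prior_init)
            ranked = rank_and_select(results, sort_key=config.sort_key,
                                     top_k=config.top_k if level == "PT"
                                     else None,
                                     exclusions=exclusions)
            path = out_dir / f"signals_{level.lower()}.csv"
            write_signal_table(ranked, path)
            manifest["outputs"].append(path.name)
            manifest["counts"][f"{level.lower()}_terms"] = len(results)
            manifest["counts"][f"{level.lower()}_significant_any"] = sum(
                r.significant_any for r in results)
            manifest["counts"][f"{level.lower()}_significant_all"] = sum(
                r.significant_all for r in results)
            manifest["counts"][f"{level.lower()}_mgps_prior"] = asdict(prior)

        # ---- cohort summary
        stage = "cohort_summary.summarize"
        summary = summarize(target_reports)
        lines = ["variable,level,count,percent"]
        for variable, rows in summary.sections:
            for row in rows:
                level_cell = (f'"{row.level}"' if "," in row.level
                              else row.level)
                lines.append(
                    f"{variable},{level_cell},{row.count},{row.percent}")
        (out_dir / "cohort_summary.csv").write_text("\n".join(lines) + "\n",
                                                    encoding="utf-8")
        manifest["outputs"].append("cohort_summary.csv")

        # ---- onset analysis
        stage = "onset_time.compute_onsets"
        records, excluded = compute_onsets(target_reports, tables["THER"].rows,
                                           drug_rows, config.target_drug)
        manifest["counts"]["onset_records"] = len(records)
        manifest["counts"]["onset_exclusions"] = dict(excluded)
        if records:
            med, q1, q3 = onset_summary(records,
                                        method=config.quantile_method)
            dist = interval_distribution(records, config.onset_bins)
            lines = ["metric,value", f"n,{len(records)}",
                     f"median_days,{med}", f"q1_days,{q1}", f"q3_days,{q3}"]
            lines += [f"share_{label},{share:.4f}"
                      for label, share in dist.items()]
            (out_dir / "onset_summary.csv").write_text(
                "\n".join(lines) + "\n", encoding="utf-8")
            manifest["outputs"].append("onset_summary.csv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str),
            encoding="utf-8")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str),
        encoding="utf-8")
    manifest["outputs"].append("manifest.json")
    return manifest
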