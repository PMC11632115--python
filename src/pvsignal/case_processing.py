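"""Case-level processing of spontaneous reports.

Steps between the raw quarterly tables and the 2x2 statistics: build one
candidate record per DEMO row, deduplicate to the latest version of each
case, standardize free-text drug names against a synonym table, select the
reports naming the study drug as primary suspect, apply the minimum
report-count filter to the drug's preferred terms, and map preferred terms
(PTs) to system organ classes (SOCs).
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .faers_io import RawRecordSet

logger = logging.getLogger(__name__)

NO_MATCH = "<no-match>"

#: FAERS outcome codes, most severe first (used by cohort_summary).
OUTCOME_SEVERITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: FAERS reporter occupation codes -> Table-1-style labels.
OCCUPATION_LABELS = {
    "PH": "Pharmacist",
    "MD": "Physician",
    "HP": "Other health-professional",
    "OT": "Other health-professional",
    "CN": "Consumer",
    "LW": "Lawyer",
}

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
DRUG_ROLES = ("PS", "SS", "C", "I")


@dataclass(frozen=True)
class SafetyReport:
    """One deduplicated case report."""

    primaryid: str
    caseid: str
    caseversion: int
    fda_date: str = ""          # partial date digit string (YYYY[MM[DD]])
    age: str = ""
    sex: str = ""
    reporter_occupation: str = "Unknown"
    reporter_country: str = ""
    event_date: str = ""
    outcomes: frozenset[str] = field(default_factory=frozenset)

    @property
    def receipt_year(self) -> int | None:
        return int(self.fda_date[:4]) if len(self.fda_date) >= 4 else None


@dataclass(frozen=True)
class DrugEventPair:
    """One (report, drug, preferred term) observation.

    A report contributes at most once to a given drug-PT cell, so the triple
    (primaryid, drug_id, pt_name) is unique within any pair list.
    """

    primaryid: str
    drug_id: str
    pt_name: str
    soc_name: str | None = None


def reports_from_raw(demo: RawRecordSet,
                     outc: RawRecordSet | None = None) -> list[SafetyReport]:
    """Build candidate :class:`SafetyReport` objects from DEMO (+OUTC) rows."""
    outcomes_by_id: dict[str, set[str]] = {}
    if outc is not None:
        for row in outc.rows:
            code = row.get("OUTC_COD", "").upper()
            if code:
                outcomes_by_id.setdefault(row["PRIMARYID"], set()).add(code)
    reports = []
    for row in demo.rows:
        try:
            version = int(row.get("CASEVERSION", "") or 1)
        except ValueError:
            version = 1
        pid = row["PRIMARYID"]
        reports.append(SafetyReport(
            primaryid=pid,
            caseid=row.get("CASEID", ""),
            caseversion=version,
            fda_date=row.get("FDA_DT", ""),
            age=row.get("AGE", ""),
            sex=row.get("SEX", "").upper() or "",
            reporter_occupation=OCCUPATION_LABELS.get(
                row.get("OCCP_COD", "").upper(), "Unknown"),
            reporter_country=row.get("REPORTER_COUNTRY", ""),
            event_date=row.get("EVENT_DT", ""),
            outcomes=frozenset(outcomes_by_id.get(pid, ())),
        ))
    return reports


def deduplicate(candidates: Iterable[SafetyReport]) -> list[SafetyReport]:
    """Keep one report per case: the latest version.

    For each caseid exactly the candidate with the highest
    ``(fda_date, caseversion, primaryid)`` lexicographic key survives, which
    realises "most recent" deterministically.  Candidates without a caseid
    are kept, keyed by primaryid, with a warning.  Output is sorted by
    caseid so the operation is order-invariant and idempotent.
    """
    best: dict[str, SafetyReport] = {}
    for cand in candidates:
        key = cand.caseid
        if not key:
            warnings.warn(
                f"report {cand.primaryid} has no caseid; kept as its own case",
                stacklevel=2)
            key = f"<primaryid:{cand.primaryid}>"
        sort_key = (cand.fda_date, cand.caseversion, cand.primaryid)
        prev = best.get(key)
        if prev is None or sort_key > (prev.fda_date, prev.caseversion,
                                       prev.primaryid):
            best[key] = cand
    return [best[k] for k in sorted(best)]


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_drug_name(name: str,
                        suffix_tokens: Sequence[str] = ("kpkc",)) -> str:
    """Case-fold, strip punctuation, collapse whitespace, drop a trailing
    biologic suffix token (e.g. the "-kpkc" of a nonproprietary biologic
    name) when it appears in *suffix_tokens*."""
    tokens = _NON_ALNUM.sub(" ", name.casefold()).split()
    if len(tokens) > 1 and tokens[-1] in {s.casefold() for s in suffix_tokens}:
        tokens = tokens[:-1]
    return " ".join(tokens)


def standardize_drug(name: str, synonym_table: Mapping[str, str],
                     suffix_tokens: Sequence[str] = ("kpkc",)) -> str:
    """Map a free-text drug name to its canonical ingredient.

    The synonym table keys are normalized variants (brand names, generic
    names, misspellings); matching is exact on the normalized string and
    unmatched names return :data:`NO_MATCH`.
    """
    key = normalize_drug_name(name, suffix_tokens)
    return synonym_table.get(key, NO_MATCH)


def normalize_synonym_table(raw: Mapping[str, str],
                            suffix_tokens: Sequence[str] = ("kpkc",),
                            ) -> dict[str, str]:
    """Normalize the lookup keys of a variant -> canonical-name table."""
    return {normalize_drug_name(k, suffix_tokens): v for k, v in raw.items()}


def standardize_drug_rows(drug: RawRecordSet, synonym_table: Mapping[str, str],
                          suffix_tokens: Sequence[str] = ("kpkc",),
                          ) -> list[dict[str, str]]:
    """Return DRUG rows augmented with a STANDARDIZED name column.

    Unmatched names fall back to their normalized form so background drugs
    without synonym entries still aggregate consistently.
    """
    out = []
    for row in drug.rows:
        name = row.get("DRUGNAME", "")
        std = standardize_drug(name, synonym_table, suffix_tokens)
        if std == NO_MATCH:
            std = normalize_drug_name(name, suffix_tokens)
        out.append({**row, "STANDARDIZED": std})
    return out


def select_suspect_reports(reports: Iterable[SafetyReport],
                           drug_rows: Iterable[Mapping[str, str]],
                           target_drug: str,
                           role_policy: str = "PS_only",
                           ) -> list[SafetyReport]:
    """Select reports naming *target_drug* in a suspect role.

    Under the default ``PS_only`` policy a report qualifies iff some drug
    row carries role code PS with the standardized target name; a report
    listing the drug several times is selected once.  ``PS_and_SS`` also
    accepts secondary-suspect rows.
    """
    if role_policy not in ("PS_only", "PS_and_SS"):
        raise ValueError(f"unknown role_policy {role_policy!r}")
    roles = {"PS"} if role_policy == "PS_only" else {"PS", "SS"}
    hit_ids = {
        row["PRIMARYID"] for row in drug_rows
        if row.get("ROLE_COD", "").upper() in roles
        and row.get("STANDARDIZED") == target_drug
    }
    return [r for r in reports if r.primaryid in hit_ids]


def suspect_drugs_by_report(drug_rows: Iterable[Mapping[str, str]],
                            role_policy: str = "PS_only",
                            ) -> dict[str, set[str]]:
    """Map primaryid -> set of standardized suspect-drug names."""
    roles = {"PS"} if role_policy == "PS_only" else {"PS", "SS"}
    out: dict[str, set[str]] = {}
    for row in drug_rows:
        if row.get("ROLE_COD", "").upper() in roles:
            out.setdefault(row["PRIMARYID"], set()).add(row["STANDARDIZED"])
    return out


def build_drug_event_pairs(reac: RawRecordSet,
                           suspect_by_report: Mapping[str, set[str]],
                           keep_ids: set[str] | None = None,
                           ) -> list[DrugEventPair]:
    """Pair every reaction row with its report's suspect drug(s).

    Pairs are deduplicated on (primaryid, drug, PT) — a report with the same
    PT recorded twice contributes once to that drug-PT cell.  *keep_ids*
    restricts to the deduplicated report set.
    """
    seen: set[tuple[str, str, str]] = set()
    pairs: list[DrugEventPair] = []
    for row in reac.rows:
        pid = row["PRIMARYID"]
        if keep_ids is not None and pid not in keep_ids:
            continue
        pt = " ".join(row.get("PT", "").split())
        if not pt:
            continue
        for drug in sorted(suspect_by_report.get(pid, ())):
            key = (pid, drug, pt)
            if key not in seen:
                seen.add(key)
                pairs.append(DrugEventPair(pid, drug, pt))
    return pairs


def apply_min_count_filter(pairs: Sequence[DrugEventPair],
                           min_count: int = 3,
                           ) -> tuple[list[DrugEventPair], dict[str, int]]:
    """Drop PTs reported by fewer than *min_count* distinct reports.

    Applied to the target drug's pairs only (the database background is not
    filtered).  Returns the retained pairs and a log of dropped PTs with
    their report counts.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    reports_per_pt: dict[str, set[str]] = {}
    for p in pairs:
        reports_per_pt.setdefault(p.pt_name, set()).add(p.primaryid)
    dropped = {pt: len(ids) for pt, ids in reports_per_pt.items()
               if len(ids) < min_count}
    if dropped:
        logger.info("min-count filter removed %d PTs: %s", len(dropped),
                    dict(sorted(dropped.items())))
    kept = [p for p in pairs if p.pt_name not in dropped]
    return kept, dropped


def load_two_column_map(path) -> dict[str, str]:
    """Read a two-column delimited mapping file (tab or comma separated)."""
    mapping: dict[str, str] = {}
    from pathlib import Path

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",", 1)
        if len(parts) != 2:
            raise ValueError(f"expected two columns, got: {line!r}")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def map_to_soc(pairs: Sequence[DrugEventPair],
               pt_soc_map: Mapping[str, str],
               unmapped_policy: str = "keep_flagged",
               ) -> tuple[list[DrugEventPair], Counter]:
    """Annotate each pair with its PT's primary system organ class.

    Every PT maps to exactly one SOC (the MedDRA primary-SOC convention).
    Unmapped PTs are dropped or kept flagged as "<unmapped>" per policy; the
    returned counter logs how many pairs each policy decision affected.
    """
    if not pt_soc_map:
        raise ValueError("PT -> SOC map is empty")
    if unmapped_policy not in ("drop", "keep_flagged"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    log: Counter = Counter()
    out: list[DrugEventPair] = []
    for p in pairs:
        soc = pt_soc_map.get(p.pt_name)
        if soc is None:
            log["unmapped"] += 1
            if unmapped_policy == "drop":
                continue
            soc = "<unmapped>"
        else:
            log["mapped"] += 1
        out.append(replace(p, soc_name=soc))
    return out, log
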