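"""Descriptive cohort summary: counts and percentages by receipt year,
reporter occupation, reporting country, and clinical outcome."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .case_processing import OUTCOME_SEVERITY, SafetyReport

#: Outcome codes -> display labels.
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


@dataclass(frozen=True)
class SummaryRow:
    level: str
    count: int
    percent: float


@dataclass(frozen=True)
class SummaryTable:
    """Sections of (variable, rows); percents recompute from counts at 2 dp."""

    sections: list[tuple[str, list[SummaryRow]]]

    def section(self, variable: str) -> list[SummaryRow]:
        for name, rows in self.sections:
            if name == variable:
                return rows
        raise KeyError(variable)

    def percent(self, variable: str, level: str) -> float:
        for row in self.section(variable):
            if row.level == level:
                return row.percent
        raise KeyError((variable, level))


def round_percent(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to 2 decimal places."""
    if denominator == 0:
        raise ValueError("zero denominator")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def most_severe_outcome(outcomes: Iterable[str]) -> str | None:
    """Pick one outcome per report by severity (DE > LT > HO > DS > ... > OT)."""
    present = set(outcomes)
    for code in OUTCOME_SEVERITY:
        if code in present:
            return code
    return None


def _section(counter: Counter, denominator: int,
             order: Sequence[str] | None = None) -> list[SummaryRow]:
    levels = list(order) if order is not None else sorted(
        counter, key=lambda k: (-counter[k], k))
    return [SummaryRow(level, counter.get(level, 0),
                       round_percent(counter.get(level, 0), denominator))
            for level in levels if counter.get(level, 0) > 0]


def top_countries(reports: Sequence[SafetyReport], k: int = 3,
                  ) -> list[SummaryRow]:
    """Top-k reporting countries with the remainder aggregated to "Other".

    Reports with no country recorded count toward "Other".  Row counts sum
    to the report total.
    """
    counts: Counter = Counter()
    for r in reports:
        counts[r.reporter_country or "Other"] += 1
    ranked = sorted((c for c in counts if c != "Other"),
                    key=lambda c: (-counts[c], c))
    top = ranked[:k]
    other = sum(counts[c] for c in ranked[k:]) + counts.get("Other", 0)
    total = len(reports)
    rows = [SummaryRow(c, counts[c], round_percent(counts[c], total))
            for c in top]
    if other > 0:
        rows.append(SummaryRow("Other", other, round_percent(other, total)))
    return rows


def summarize(reports: Sequence[SafetyReport], n_countries: int = 3,
              ) -> SummaryTable:
    """Build the descriptive summary over a deduplicated, drug-selected cohort.

    Year, reporter and country sections use all reports as denominator.  The
    outcome section assigns each report its single most severe outcome and
    uses the number of outcome-classified reports as denominator, so a
    report with several recorded outcomes is counted once.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    total = len(reports)

    years = Counter(str(r.receipt_year) for r in reports
                    if r.receipt_year is not None)
    reporters = Counter(r.reporter_occupation for r in reports)

    outcome_counts: Counter = Counter()
    for r in reports:
        worst = most_severe_outcome(r.outcomes)
        if worst is not None:
            outcome_counts[OUTCOME_LABELS[worst]] += 1
    n_outcome = sum(outcome_counts.values())

    sections = [
        ("Year", _section(years, total, order=sorted(years))),
        ("Reporter", _section(reporters, total)),
        ("Reported countries", top_countries(reports, n_countries)),
        ("Outcomes", _section(outcome_counts, n_outcome) if n_outcome else []),
    ]
    return SummaryTable(sections=sections)


def healthcare_professional_percent(summary: SummaryTable) -> float:
    """Share of reports from pharmacists, physicians and other health
    professionals (recomputed from the reporter section counts)."""
    rows = summary.section("Reporter")
    total = sum(r.count for r in rows)
    pro = sum(r.count for r in rows
              if r.level in ("Pharmacist", "Physician",
                             "Other health-professional"))
    return round_percent(pro, total)


def cohort_from_counts(year_counts: dict[str, int],
                       reporter_counts: dict[str, int],
                       country_counts: dict[str, int],
                       outcome_counts: dict[str, int],
                       n_no_outcome: int = 0) -> list[SafetyReport]:
    """Construct a synthetic cohort realising given marginal counts.

    Utility for desk checks: builds minimal reports whose year, reporter,
    country and outcome marginals equal the supplied counts (each report
    gets at most one outcome).  The marginal totals for year, reporter and
    country must agree; outcomes plus *n_no_outcome* must match that total.
    """
    label_to_code = {v: k for k, v in OUTCOME_LABELS.items()}
    totals = {sum(year_counts.values()), sum(reporter_counts.values()),
              sum(country_counts.values()),
              sum(outcome_counts.values()) + n_no_outcome}
    if len(totals) != 1:
        raise ValueError(f"marginal totals disagree: {sorted(totals)}")
    n = totals.pop()

    def expand(counts: dict[str, int]) -> list[str]:
        out: list[str] = []
        for level, count in counts.items():
            out.extend([level] * count)
        return out

    years = expand(year_counts)
    occupations = expand(reporter_counts)
    countries = expand(country_counts)
    outcomes = expand(outcome_counts) + [""] * n_no_outcome
    reports = []
    for i in range(n):
        code = label_to_code.get(outcomes[i], outcomes[i])
        reports.append(SafetyReport(
            primaryid=str(100000 + i), caseid=str(100000 + i), caseversion=1,
            fda_date=f"{years[i]}0101",
            reporter_occupation=occupations[i],
            reporter_country=countries[i],
            outcomes=frozenset({code}) if code else frozenset(),
        ))
    return reports
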