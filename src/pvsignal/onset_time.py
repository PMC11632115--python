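"""Time-to-onset analysis: days from first therapy start to event onset.

Spontaneous reports carry partial dates (YYYY, YYYYMM or YYYYMMDD digit
strings); only full 8-digit dates support day arithmetic, so records with
partial or missing dates, or a negative interval, are excluded and counted
by reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np

from .case_processing import SafetyReport

#: Default interval edges (days): within week 1 / month 1 / month 2 / later.
DEFAULT_EDGES = (7, 30, 60)


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    therapy_start: str   # YYYYMMDD
    event_date: str      # YYYYMMDD
    days: int

    def __post_init__(self) -> None:
        if self.days < 0:
            raise ValueError("onset interval must be non-negative")


def _parse_full_date(s: str) -> date | None:
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def compute_onsets(reports: Iterable[SafetyReport],
                   ther_rows: Iterable[Mapping[str, str]],
                   drug_rows: Iterable[Mapping[str, str]],
                   target_drug: str,
                   ) -> tuple[list[OnsetRecord], Counter]:
    """Compute onset intervals for the target drug's reports.

    The start date is the earliest full therapy-start date among the target
    drug's therapy episodes in each report (time to first onset when several
    episodes exist); the end date is the report's event date.  Returns the
    usable records plus an exclusion log keyed by reason.
    """
    # therapy rows join DRUG rows on (primaryid, drug sequence number)
    target_seqs: set[tuple[str, str]] = {
        (row["PRIMARYID"], row.get("DRUG_SEQ", ""))
        for row in drug_rows if row.get("STANDARDIZED") == target_drug
    }
    starts: dict[str, list[str]] = {}
    for row in ther_rows:
        key = (row["PRIMARYID"], row.get("DSG_DRUG_SEQ", ""))
        if key in target_seqs:
            starts.setdefault(row["PRIMARYID"], []).append(
                row.get("START_DT", ""))

    records: list[OnsetRecord] = []
    excluded: Counter = Counter()
    for report in reports:
        report_starts = [s for s in starts.get(report.primaryid, []) if s]
        if not report_starts:
            excluded["missing start date"] += 1
            continue
        full_starts = sorted(s for s in report_starts
                             if _parse_full_date(s) is not None)
        if not full_starts:
            excluded["partial start date"] += 1
            continue
        start_str = full_starts[0]
        if not report.event_date:
            excluded["missing event date"] += 1
            continue
        event = _parse_full_date(report.event_date)
        if event is None:
            excluded["partial event date"] += 1
            continue
        days = (event - _parse_full_date(start_str)).days
        if days < 0:
            excluded["negative interval"] += 1
            continue
        records.append(OnsetRecord(report.primaryid, start_str,
                                   report.event_date, days))
    return records, excluded


def onset_summary(records: Sequence[OnsetRecord] | Sequence[int],
                  method: str = "linear") -> tuple[float, float, float]:
    """Median and quartiles of the onset intervals.

    *method* selects the quantile convention (any accepted by
    ``numpy.quantile``); the default linearly interpolates between order
    statistics.  Returns ``(median, q1, q3)``.
    """
    days = np.array([r.days if isinstance(r, OnsetRecord) else r
                     for r in records], dtype=float)
    if days.size == 0:
        raise ValueError("no onset records")
    q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75], method=method)
    return float(med), float(q1), float(q3)


def interval_labels(edges: Sequence[int] = DEFAULT_EDGES) -> list[str]:
    labels = [f"<={edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def interval_distribution(records: Sequence[OnsetRecord] | Sequence[int],
                          edges: Sequence[int] = DEFAULT_EDGES,
                          ) -> dict[str, float]:
    """Percentage of onsets per interval bin.

    Bins are inclusive on the right of each listed edge: with the default
    edges a 30-day onset falls in "8-30" and a 31-day onset in "31-60".
    The shares form a partition of unity (here scaled to 100%).
    """
    days = np.array([r.days if isinstance(r, OnsetRecord) else r
                     for r in records], dtype=float)
    if days.size == 0:
        raise ValueError("no onset records")
    if list(edges) != sorted(set(edges)):
        raise ValueError("edges must be strictly increasing")
    idx = np.searchsorted(np.asarray(edges, dtype=float), days, side="left")
    labels = interval_labels(edges)
    counts = np.bincount(idx, minlength=len(labels))
    return {lab: 100.0 * c / days.size for lab, c in zip(labels, counts)}


def cumulative_onset_curve(records: Sequence[OnsetRecord] | Sequence[int],
                           ) -> list[tuple[int, float]]:
    """(day, cumulative share) points of the empirical onset distribution."""
    days = sorted(r.days if isinstance(r, OnsetRecord) else r
                  for r in records)
    if not days:
        raise ValueError("no onset records")
    n = len(days)
    curve = []
    for i, d in enumerate(days, start=1):
        if i == n or days[i] != d:
            curve.append((d, i / n))
    return curve
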