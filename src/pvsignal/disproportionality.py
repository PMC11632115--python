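"""Frequentist disproportionality statistics on 2x2 contingency tables.

Each drug-event pair is summarised against the database background as

                 target event    other events
    target drug       a               b
    other drugs       c               d

with N = a+b+c+d report-event pairs in total.  The reporting odds ratio
(ROR = ad/bc) and proportional reporting ratio (PRR) carry log-scale Wald
95% confidence intervals; the chi-squared statistic defaults to the Yates
continuity-corrected form.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .case_processing import DrugEventPair

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.N == 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass(frozen=True)
class SignalThresholds:
    """Signal criteria for the four algorithms (conventional defaults)."""

    min_count: int = 3          # a >= 3 gates ROR and PRR signals
    ror_ci_low: float = 1.0     # ROR 95% CI lower bound > 1
    prr_min: float = 2.0        # PRR >= 2
    chi2_min: float = 4.0       # chi-squared >= 4
    ic025_min: float = 0.0      # IC025 > 0
    ebgm05_min: float = 2.0     # EBGM05 > 2


@dataclass(frozen=True)
class FrequentistStats:
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    ror_defined: bool = True
    prr_defined: bool = True
    chi2_defined: bool = True
    ror_signal: bool = False
    prr_signal: bool = False


def build_tables(pairs: Sequence[DrugEventPair], level: str,
                 target_drug: str) -> dict[str, ContingencyTable]:
    """Tally one 2x2 table per term for *target_drug* vs the background.

    *level* selects the term axis: ``"PT"`` uses preferred terms, ``"SOC"``
    uses the mapped system organ class, so a SOC's count is the number of
    report-PT pairs falling in that SOC (a report with two PTs in one SOC
    contributes 2).  N is identical across terms.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")

    def term_of(p: DrugEventPair) -> str | None:
        return p.pt_name if level == "PT" else p.soc_name

    target_terms: Counter = Counter()
    background_terms: Counter = Counter()
    for p in pairs:
        term = term_of(p)
        if term is None:
            raise ValueError(f"pair {p} has no SOC; run map_to_soc first")
        (target_terms if p.drug_id == target_drug else background_terms)[term] += 1
    if not target_terms:
        raise ValueError(f"target drug {target_drug!r} absent from pairs")

    n_target = sum(target_terms.values())
    n_background = sum(background_terms.values())
    tables = {}
    for term in sorted(set(target_terms) | set(background_terms)):
        a = target_terms.get(term, 0)
        c = background_terms.get(term, 0)
        tables[term] = ContingencyTable(a, n_target - a, c, n_background - c)
    return tables


def ror_with_ci(t: ContingencyTable, z: float = Z_95,
                ) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio ad/bc with a log-scale Wald CI.

    Undefined (NaN) when any cell is zero; no continuity correction is
    applied by default.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return math.nan, (math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, (ror * math.exp(-z * se), ror * math.exp(z * se))


def prr_with_ci(t: ContingencyTable, z: float = Z_95,
                ) -> tuple[float, tuple[float, float]]:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with Wald CI."""
    if t.c == 0 or t.a == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return math.nan, (math.nan, math.nan)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return prr, (prr * math.exp(-z * se), prr * math.exp(z * se))


def chi_squared(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-squared on the 2x2 table.

    With the Yates continuity correction the statistic is
    N(|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), floored at 0 when
    |ad-bc| <= N/2.  Undefined (NaN) on a zero margin.
    """
    n = t.N
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        return math.nan
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


def frequentist_flags(t: ContingencyTable, stats: FrequentistStats,
                      thresholds: SignalThresholds = SignalThresholds(),
                      ) -> FrequentistStats:
    """Apply the conventional ROR and PRR signal criteria.

    ror_signal: a >= 3 and the ROR 95% CI lower bound exceeds 1.
    prr_signal: a >= 3, PRR >= 2 and chi-squared >= 4 (inclusive bounds).
    """
    from dataclasses import replace

    gate = t.a >= thresholds.min_count
    ror_signal = bool(gate and stats.ror_defined
                      and stats.ror_ci[0] > thresholds.ror_ci_low)
    prr_signal = bool(gate and stats.prr_defined and stats.chi2_defined
                      and stats.prr >= thresholds.prr_min
                      and stats.chi2 >= thresholds.chi2_min)
    return replace(stats, ror_signal=ror_signal, prr_signal=prr_signal)


def frequentist_stats(t: ContingencyTable,
                      thresholds: SignalThresholds = SignalThresholds(),
                      yates: bool = True, z: float = Z_95) -> FrequentistStats:
    """Compute ROR, PRR, chi-squared and their signal flags for one table."""
    ror, ror_ci = ror_with_ci(t, z)
    prr, prr_ci = prr_with_ci(t, z)
    chi2 = chi_squared(t, yates)
    stats = FrequentistStats(
        ror=ror, ror_ci=ror_ci, prr=prr, prr_ci=prr_ci, chi2=chi2,
        ror_defined=not math.isnan(ror),
        prr_defined=not math.isnan(prr),
        chi2_defined=not math.isnan(chi2),
    )
    return frequentist_flags(t, stats, thresholds)
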