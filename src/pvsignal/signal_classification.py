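"""Merge the four disproportionality algorithms into signal rows, apply the
joint significance rule, and rank/format result tables."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .disproportionality import (ContingencyTable, FrequentistStats,
                                 SignalThresholds, frequentist_stats)
from .empirical_bayes import (BcpnnResult, GammaMixturePrior, MgpsResult,
                              bcpnn_ic, fit_mgps_prior, mgps_score)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalResult:
    """One row of a signal table: all four algorithms for one term."""

    term: str
    level: str                 # "PT" or "SOC"
    n: int                     # the contingency a cell
    frequentist: FrequentistStats
    bcpnn: BcpnnResult
    mgps: MgpsResult
    significant_any: bool
    significant_all: bool


def classify(term: str, level: str, table: ContingencyTable,
             frequentist: FrequentistStats, bcpnn: BcpnnResult,
             mgps: MgpsResult) -> SignalResult:
    """Combine the four algorithm flags for one term.

    ``significant_any`` is the OR of the four flags (a term is a signal for
    at least one algorithm); ``significant_all`` is the AND (meets the
    criteria of all four).
    """
    for name, value in (("frequentist", frequentist), ("bcpnn", bcpnn),
                        ("mgps", mgps)):
        if value is None:
            raise ValueError(f"missing {name} output for term {term!r}")
    flags = (frequentist.ror_signal, frequentist.prr_signal, bcpnn.flag,
             mgps.flag)
    return SignalResult(
        term=term, level=level, n=table.a,
        frequentist=frequentist, bcpnn=bcpnn, mgps=mgps,
        significant_any=any(flags), significant_all=all(flags),
    )


def score_tables(tables: Mapping[str, ContingencyTable], level: str,
                 thresholds: SignalThresholds = SignalThresholds(),
                 yates: bool = True,
                 prior: GammaMixturePrior | None = None,
                 prior_init: GammaMixturePrior = GammaMixturePrior(),
                 ) -> tuple[list[SignalResult], GammaMixturePrior]:
    """Run all four algorithms over a full set of contingency tables.

    The MGPS prior is fitted on all pairs unless a fitted *prior* is passed
    in (e.g. a PT-level prior reused at SOC level).  Returns the classified
    rows sorted by term, plus the prior actually used.
    """
    terms = sorted(tables)
    if prior is None:
        counts = np.array([tables[t].a for t in terms], dtype=float)
        expecteds = np.array([tables[t].expected for t in terms])
        prior = fit_mgps_prior(counts, expecteds, init=prior_init)
    results = []
    for term in terms:
        t = tables[term]
        results.append(classify(
            term, level, t,
            frequentist_stats(t, thresholds, yates=yates),
            bcpnn_ic(t, ic025_min=thresholds.ic025_min),
            mgps_score(t, prior, ebgm05_min=thresholds.ebgm05_min),
        ))
    return results, prior


def rank_and_select(results: Sequence[SignalResult], sort_key: str = "ror",
                    top_k: int | None = None,
                    exclusions: Iterable[str] = (),
                    ) -> list[SignalResult]:
    """Exclude listed terms, sort descending, truncate to *top_k*.

    The exclusion list removes terms attributable to the underlying disease
    rather than the drug (supplied by the analyst, e.g. "Disease
    progression").  Ties break by larger n, then term name; the sort is
    stable so no terms are created or lost except the stated exclusions and
    truncation.
    """
    if sort_key not in ("ror", "n"):
        raise ValueError(f"sort_key must be 'ror' or 'n', got {sort_key!r}")
    excluded = set(exclusions)

    def key(r: SignalResult) -> tuple:
        primary = r.n if sort_key == "n" else (
            -math.inf if math.isnan(r.frequentist.ror) else r.frequentist.ror)
        return (-primary, -r.n, r.term)

    kept = sorted((r for r in results if r.term not in excluded), key=key)
    return kept[:top_k] if top_k is not None else kept


def forest_plot_data(results: Sequence[SignalResult],
                     terms: Iterable[str],
                     ) -> tuple[list[dict], list[str]]:
    """Extract (term, n, ROR, CI) rows for a forest plot over chosen terms.

    Values pass through from the signal rows unchanged.  Terms absent from
    the results, or with a non-positive CI lower bound (not plottable on a
    log axis), are returned in the skipped list.
    """
    by_term = {r.term: r for r in results}
    rows, skipped = [], []
    for term in terms:
        r = by_term.get(term)
        if r is None:
            skipped.append(term)
            continue
        f = r.frequentist
        if not f.ror_defined or not f.ror_ci[0] > 0:
            skipped.append(term)
            continue
        rows.append({"term": r.term, "n": r.n, "ror": f.ror,
                     "ci_low": f.ror_ci[0], "ci_high": f.ror_ci[1]})
    if skipped:
        logger.info("forest plot skipped terms: %s", skipped)
    return rows, skipped
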