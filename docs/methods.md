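# Methods

## Data model and processing conventions

A *case* is one patient-event narrative; FAERS distributes it as rows in
five `$`-delimited quarterly tables (DEMO, DRUG, REAC, OUTC, THER) joined
by `primaryid`, where `primaryid` encodes `caseid` plus a version number.
The format has no quoting mechanism, so the parser treats `$` as a hard
delimiter and the writer rejects fields containing it. Identifiers stay
text (leading zeros are significant); partial dates stay digit strings
(`YYYY`, `YYYYMM`, `YYYYMMDD`) until arithmetic is actually needed.

**Deduplication.** Regulators re-transmit cases as new versions; only the
latest version should be analyzed. "Most recent" is made deterministic by
keeping, per `caseid`, the maximum of the lexicographic key
`(fda_date, caseversion, primaryid)`. The operation is idempotent and
order-invariant; candidates without a `caseid` are retained keyed by
`primaryid` with a warning rather than silently dropped.

**Drug-name standardization.** FAERS `DRUGNAME` is free text. Names are
case-folded, punctuation is collapsed to spaces, and a trailing biologic
suffix token (the FDA's 4-letter nonproprietary suffixes, e.g. `-kpkc`)
is dropped before an exact lookup in a user-supplied synonym table.
Unmatched names are flagged rather than guessed; in the pipeline they
fall back to their normalized form so background drugs aggregate
consistently without a synonym entry.

**Counting unit.** The statistics count *report–event pairs*: a report
contributes at most once to a given drug–PT cell, a report with k
distinct PTs contributes k pairs, and a SOC's count is the sum over its
member PTs (so one report can contribute more than once to a SOC). The
comparator for every 2×2 table is all other suspect drugs in the corpus;
N is identical across terms at a given level.

**Minimum-count filter.** PTs reported by fewer than 3 distinct reports
for the target drug are removed before scoring (configurable). The filter
applies to the target drug's pairs only — the background is never
filtered, since rare-event behaviour of the background is exactly what
the empirical-Bayes prior must see.

## The four algorithms

ROR, PRR and χ² are the standard frequentist closed forms (log-scale Wald
intervals with z = 1.96; Yates continuity correction on by default, with
a switch, since published analyses rarely state the variant). Zero cells
make ROR/PRR undefined; results are flagged as undefined rather than
continuity-corrected by default, because a 0.5 imputation silently
inflates rare-event signals.

**BCPNN.** The information component uses the classical closed-form
posterior approximation with hyperparameters α₁ = β₁ = 1, α = β = 2,
γ₁₁ = 1 and γ scaled to the margins:

    IC = log₂ [(a+1)(N+2)² / ((N+γ)(a+b+1)(a+c+1))],
    γ  = (N+2)² / ((a+b+1)(a+c+1)),

with the matching variance expression and IC025 = IC − 2·sd. This closed
form is log₂ of a ratio of posterior means, not the posterior mean of the
log-ratio; for cells of a handful of reports the two differ by roughly
1/(2a·ln 2) bits, which is why the Monte-Carlo cross-check in the test
suite uses a table that is small relative to the database (a = 100 of
N = 10⁵) rather than a = 3, where a 0.01-bit agreement would be
unattainable for any implementation of this closed form. IC025 as
"mean − 2 sd" matches the conventional column naming; a Norén-style
gamma-approximation credible interval would shift IC025 in the second
decimal for small a and is out of scope.

**MGPS.** Observed counts are modelled as a ~ Poisson(λE) with
λ ~ w·Ga(α₁,β₁) + (1−w)·Ga(α₂,β₂). Marginally a is a two-component
negative-binomial mixture; the five hyperparameters are fitted by
maximizing the summed log marginal likelihood with L-BFGS-B in
unconstrained space (log for positives, logit for w), starting from the
conventional (w=1/3, α₁=0.2, β₁=0.1, α₂=2, β₂=4). The fit is
deterministic given data and start; a non-converged fit returns
best-so-far with a warning, and the returned point is never worse than
the start. The posterior per pair is again a gamma mixture;
EBGM = 2^(E[log₂λ]) via the digamma closed form per component, and EBGM05
solves posterior-CDF(λ) = 0.05 by Brent root-finding (relative tolerance
1e-12, bracket [1e-12, max(rr,1)·10³], expanded upward if needed; when a
near-zero fitted shape puts over 5% of mass below the bracket floor,
EBGM05 is reported as 0). No stratification ("squashing") is applied: the
prior is fitted on the full pair table. The gamma-mixture likelihood is
invariant to component relabelling, so recovery diagnostics compare
mixture CDFs (Kolmogorov distance) or align components before comparing
parameters.

**Joint rule.** `significant_any` = OR and `significant_all` = AND of
{ROR CI low > 1 with a ≥ 3; PRR ≥ 2 & χ² ≥ 4 with a ≥ 3; IC025 > 0;
EBGM05 > 2}. All thresholds are configurable; the defaults are the
criteria used across the FAERS disproportionality literature. Exclusion
of disease-attributable terms (e.g. "Disease progression") is a
user-supplied list, not a hard-coded ontology.

## Cohort summary and onset analysis

Year, reporter-occupation and country sections use all selected reports
as denominator; countries beyond the top k aggregate to "Other".
Outcomes are counted one-per-report by severity priority
DE > LT > HO > DS > CA > RI > OT, with the number of outcome-classified
reports as denominator — reports without any outcome code are excluded
from that section only. This convention is recorded here because outcome
tables in published cohorts often sum to fewer than the report total,
which is exactly what one-most-severe-per-report over classified reports
produces. Percentages are rounded half-up to 2 decimal places.

Time to onset uses only 8-digit dates: the earliest full therapy-start
date of the target drug in a report (time to *first* onset when several
episodes exist) to the report's event date. Partial or missing dates and
negative intervals are excluded and counted by reason. Quartiles default
to linear interpolation between order statistics, with the numpy quantile
method exposed because published IQRs rarely state a convention and small
samples are sensitive to it (for [2, 21, 107], linear gives (11.5, 64)
while the inverted-CDF convention gives (2, 107)). Interval bins are
right-inclusive at the configured edges (default 7/30/60 days: day 30
falls in "8–30", day 31 in "31–60").

## The synthetic generator

`synthetic_faers.generate` emulates the features the pipeline must
survive, with ground truth kept outside the FAERS-format files:

- one DEMO/THER row and one PS DRUG row per report, plus Poisson(0.7)
  concomitant drugs; the target drug's name is drawn from brand /
  generic / suffixed variants to exercise standardization;
- event inclusion is Bernoulli per (report, event) with probability
  proportional to a power-law popularity (exponent 1.1 over 200 events,
  scaled to 3.1 PTs per report on average, matching a pair-to-report
  ratio of ≈3.1), multiplied by planted rate factors λ for chosen
  (drug, event) pairs — optionally by draws from a gamma-mixture prior
  for recovery experiments;
- 10% of cases are re-emitted as a second version (the duplicate map is
  ground truth for the deduplication test);
- receipt quarters follow the observed year mix of the example cohort
  (2018Q4–2023Q4); reporter, country and outcome fields follow its
  marginal distributions, with age/sex largely missing as in real data;
- onset gaps are lognormal with median 21 days and σ = 2.9 (σ chosen so
  the log-scale IQR width matches the observed 2–107-day spread), with a
  configurable fraction of therapy-start dates degraded to `YYYYMM` and
  a small rate of injected negative intervals.

What the generator does *not* emulate: correlated events within a report
(PTs are independent given the drug), indication/dose records, free-text
misspellings beyond the listed variants, country-specific reporting
styles, or secular trends in reporting rates. A lognormal with a single σ
also cannot reproduce an IQR that is asymmetric around the median on the
log scale (2–107 around 21 implies a heavier immediate-onset spike than
delayed tail); the generated quartiles are therefore symmetric on the log
scale around 21 days. Consequently, passing end-to-end tests demonstrate
correct mechanics and calibration of the statistics under a known model —
not that real FAERS data meet these assumptions.

Default scale (5000 reports, 40 background drugs, 200 events, 10% target
share) keeps a full generate-ingest-score cycle around one second while
giving planted λ = 10 signals comfortably detectable counts; the
prior-recovery experiment uses 50,000 directly simulated (a, E) pairs,
the scale at which all five hyperparameters become identifiable.

## Numerical choices and degenerate inputs

- Mixture likelihoods are evaluated with `logaddexp`; non-finite
  parameter proposals score −∞ rather than aborting the optimizer.
- Convergence: L-BFGS-B `ftol` 1e-8 relative improvement; the fit warns
  below 100 pairs (SOC-level tables) instead of refusing.
- `ContingencyTable` rejects negative cells and empty tables at
  construction; `build_tables` requires the target drug to be present.
- Ranking ties break by larger n, then term name, so output order is
  fully deterministic; the pipeline consumes no randomness outside the
  generator, and re-runs are byte-identical.
- Chi-squared with Yates is floored at zero when |ad−bc| ≤ N/2.

## Known limitations

- Disproportionality quantifies reporting association, not risk; no
  causal or incidence claims follow from any flag.
- No stratified or regression-adjusted variants (age/sex stratification,
  Norén credible intervals, itemset MGPS) — out of scope.
- The synonym table and PT→SOC map are user inputs; the package ships
  only the synthetic variants (real MedDRA is licensed and not
  redistributable).
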