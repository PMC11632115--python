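"""Synthetic FAERS-format corpus generator with known ground truth.

Emulates the features of a quarterly spontaneous-reporting extract that the
pipeline must survive: multi-table reports keyed by a shared identifier,
duplicate case versions, a designated suspect drug appearing under brand /
generic / suffixed name variants, Poisson-like drug-event counts with
planted rate multipliers, demographic and outcome fields with missingness,
and full or partial therapy-start and event-onset dates.

Event popularity follows a power law so that rare events — where empirical
Bayes shrinkage matters most — are represented.  Ground truth (planted
signals, the duplicate map, per-event target counts) is returned separately
and never embedded in the FAERS-format files.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .empirical_bayes import GammaMixturePrior
from .faers_io import RawRecordSet, write_quarter

TARGET_CANONICAL = "mogamulizumab"

#: Name variants under which the suspect drug appears in DRUGNAME free text.
TARGET_NAME_VARIANTS = ("MOGAMULIZUMAB", "POTELIGEO", "Mogamulizumab-kpkc",
                        "mogamulizumab ")

#: System organ classes used for the synthetic PT -> SOC map (MedDRA-style
#: primary SOC names).
SOC_NAMES = (
    "Skin and subcutaneous tissue disorders",
    "General disorders and administration site conditions",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Gastrointestinal disorders",
    "Investigations",
    "Blood and lymphatic system disorders",
    "Nervous system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Metabolism and nutrition disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Immune system disorders",
    "Cardiac disorders",
    "Psychiatric disorders",
    "Hepatobiliary disorders",
    "Neoplasms benign, malignant and unspecified",
    "Vascular disorders",
    "Renal and urinary disorders",
    "Eye disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Reproductive system and breast disorders",
    "Congenital, familial and genetic disorders",
)

QUARTERS = tuple(f"{y}Q{q}" for y in range(2018, 2024) for q in range(1, 5)
                 if (y, q) >= (2018, 4))

_YEAR_WEIGHTS = {"2018": 19, "2019": 209, "2020": 193, "2021": 254,
                 "2022": 326, "2023": 181}
_OCCUPATION_WEIGHTS = {"PH": 722, "MD": 240, "HP": 161, "CN": 58, "": 1}
_COUNTRY_WEIGHTS = {"US": 694, "JP": 211, "FR": 98, "DE": 45, "GB": 40,
                    "IT": 34, "CA": 30, "AU": 30}
_OUTCOME_WEIGHTS = {"HO": 225, "DE": 197, "LT": 35, "DS": 9, "OT": 546,
                    "": 170}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror a mogamulizumab-sized reporting cohort scaled to desk
    size: ~3.1 preferred terms per report, year / reporter / country /
    outcome mixes matching the observed cohort margins, 10% duplicate case
    versions, and onset gaps lognormal with median 21 days.
    """

    seed: int = 0
    n_reports: int = 5000
    n_drugs: int = 40
    n_events: int = 200
    background_rate: float = 3.1
    target_drug_share: float = 0.1
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    prior_for_multipliers: GammaMixturePrior | None = None
    duplicate_fraction: float = 0.1
    partial_date_fraction: float = 0.15
    negative_gap_fraction: float = 0.02
    onset_median_days: float = 21.0
    onset_log_sigma: float = 2.9
    popularity_exponent: float = 1.1
    year_weights: dict = field(default_factory=lambda: dict(_YEAR_WEIGHTS))
    occupation_weights: dict = field(
        default_factory=lambda: dict(_OCCUPATION_WEIGHTS))
    country_weights: dict = field(
        default_factory=lambda: dict(_COUNTRY_WEIGHTS))
    outcome_weights: dict = field(
        default_factory=lambda: dict(_OUTCOME_WEIGHTS))

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.n_drugs < 1 or self.n_reports < 1:
            raise ValueError("n_reports, n_drugs and n_events must be >= 1")
        for frac in (self.target_drug_share, self.duplicate_fraction,
                     self.partial_date_fraction, self.negative_gap_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for _, _, lam in self.planted_signals:
            if lam <= 0:
                raise ValueError("planted rate multipliers must be positive")


def event_names(n: int) -> list[str]:
    return [f"Event {i:03d}" for i in range(1, n + 1)]


def drug_names(n: int) -> list[str]:
    """Background drug ids; the target drug is handled separately."""
    return [f"drug {i:02d}" for i in range(1, n + 1)]


def default_synonym_table() -> dict[str, str]:
    """Variant -> canonical entries for the target drug."""
    return {v.strip(): TARGET_CANONICAL for v in TARGET_NAME_VARIANTS}


def make_pt_soc_map(events: list[str], rng: np.random.Generator,
                    ) -> dict[str, str]:
    """Assign each synthetic PT a primary SOC."""
    socs = rng.choice(len(SOC_NAMES), size=len(events))
    return {e: SOC_NAMES[s] for e, s in zip(events, socs)}


def sample_gamma_mixture(prior: GammaMixturePrior, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw rate multipliers from a two-component gamma mixture."""
    comp1 = rng.random(n) < prior.w
    lam = np.where(
        comp1,
        rng.gamma(prior.alpha1, 1.0 / prior.beta1, size=n),
        rng.gamma(prior.alpha2, 1.0 / prior.beta2, size=n))
    return lam


def sample_onset_gaps(n: int, median_days: float, log_sigma: float,
                      rng: np.random.Generator,
                      max_days: int = 3650) -> np.ndarray:
    """Lognormal onset gaps (days, integer, >= 0).

    The far tail is clipped at *max_days* (10 years by default) so therapy
    start dates stay on the calendar; the clip only moves mass within the
    top interval bin.
    """
    gaps = rng.lognormal(mean=np.log(median_days), sigma=log_sigma, size=n)
    return np.minimum(np.floor(gaps), max_days).astype(int)


def _quarter_bounds(label: str) -> tuple[date, date]:
    year, q = int(label[:4]), int(label[-1])
    month0 = 3 * (q - 1) + 1
    last_month = month0 + 2
    return (date(year, month0, 1),
            date(year, last_month, calendar.monthrange(year, last_month)[1]))


def quarter_of(yyyymmdd: str) -> str:
    y, m = int(yyyymmdd[:4]), int(yyyymmdd[4:6])
    return f"{y}Q{(m - 1) // 3 + 1}"


def _dt(d: date) -> str:
    return d.strftime("%Y%m%d")


def generate(config: SimConfig) -> tuple[dict[str, RawRecordSet], dict]:
    """Generate one corpus: five FAERS-style tables plus ground truth.

    The returned record sets span the whole study window (rows carry their
    quarter through FDA_DT); :func:`write_corpus` splits them into quarterly
    file sets.  The same seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    events = event_names(config.n_events)
    drugs = drug_names(config.n_drugs)
    n = config.n_reports

    # --- event popularity (power law) and base inclusion probabilities
    ranks = np.arange(1, config.n_events + 1, dtype=float)
    popularity = ranks ** -config.popularity_exponent
    popularity /= popularity.sum()
    base_prob = np.minimum(config.background_rate * popularity, 0.9)

    # --- per-report suspect drug
    is_target = rng.random(n) < config.target_drug_share
    bg_choice = rng.integers(0, config.n_drugs, size=n)
    ps_drug = np.where(is_target, TARGET_CANONICAL,
                       np.array(drugs, dtype=object)[bg_choice])

    # --- rate multipliers: optional gamma-mixture draw per (drug, event),
    #     explicit planted signals override
    event_index = {e: j for j, e in enumerate(events)}
    all_drugs = [TARGET_CANONICAL] + drugs
    mult_by_drug = {d: np.ones(config.n_events) for d in all_drugs}
    if config.prior_for_multipliers is not None:
        lam = sample_gamma_mixture(config.prior_for_multipliers,
                                   len(all_drugs) * config.n_events, rng)
        lam = lam.reshape(len(all_drugs), config.n_events)
        for i, d in enumerate(all_drugs):
            mult_by_drug[d] = lam[i]
    for drug, event, lam_value in config.planted_signals:
        if event not in event_index:
            raise ValueError(f"planted event {event!r} not in event list")
        if drug not in mult_by_drug:
            raise ValueError(f"planted drug {drug!r} not in drug list")
        mult_by_drug[drug] = mult_by_drug[drug].copy()
        mult_by_drug[drug][event_index[event]] = lam_value

    probs = np.empty((n, config.n_events))
    for i in range(n):
        probs[i] = np.minimum(base_prob * mult_by_drug[ps_drug[i]], 0.95)
    hits = rng.random((n, config.n_events)) < probs
    # every report carries at least one reaction
    empty = ~hits.any(axis=1)
    forced = rng.choice(config.n_events, size=int(empty.sum()), p=popularity)
    hits[np.flatnonzero(empty), forced] = True

    # --- dates: receipt quarter by year mix, onset gap lognormal
    years = list(config.year_weights)
    yw = np.array([config.year_weights[y] for y in years], dtype=float)
    year_draw = rng.choice(len(years), size=n, p=yw / yw.sum())
    gaps = sample_onset_gaps(n, config.onset_median_days,
                             config.onset_log_sigma, rng)
    negative = rng.random(n) < config.negative_gap_fraction
    partial_start = rng.random(n) < config.partial_date_fraction
    delays = rng.integers(0, 61, size=n)

    occ_levels = list(config.occupation_weights)
    ow = np.array([config.occupation_weights[o] for o in occ_levels],
                  dtype=float)
    occ_draw = rng.choice(len(occ_levels), size=n, p=ow / ow.sum())
    country_levels = list(config.country_weights)
    cw = np.array([config.country_weights[c] for c in country_levels],
                  dtype=float)
    country_draw = rng.choice(len(country_levels), size=n, p=cw / cw.sum())
    outcome_levels = list(config.outcome_weights)
    ucw = np.array([config.outcome_weights[o] for o in outcome_levels],
                   dtype=float)
    outcome_draw = rng.choice(len(outcome_levels), size=n, p=ucw / ucw.sum())
    sex_draw = rng.choice(3, size=n, p=[0.35, 0.35, 0.30])
    variant_draw = rng.integers(0, len(TARGET_NAME_VARIANTS), size=n)
    n_concom = rng.poisson(0.7, size=n)
    dup_flags = rng.random(n) < config.duplicate_fraction

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    truth_pair_counts: dict[str, int] = {}
    duplicate_map: dict[str, list[str]] = {}

    for i in range(n):
        caseid = str(10_000_000 + i)
        primaryid = caseid + "1"
        year = years[year_draw[i]]
        q_choices = [q for q in QUARTERS if q.startswith(year)]
        quarter = q_choices[int(rng.integers(0, len(q_choices)))]
        q_start, q_end = _quarter_bounds(quarter)
        fda = q_start + timedelta(days=int(
            rng.integers(0, (q_end - q_start).days + 1)))
        event_dt = fda - timedelta(days=int(delays[i]))
        if negative[i]:
            start_dt = event_dt + timedelta(days=int(rng.integers(1, 31)))
        else:
            start_dt = event_dt - timedelta(days=int(gaps[i]))
        start_str = _dt(start_dt)[:6] if partial_start[i] else _dt(start_dt)

        drugname = (TARGET_NAME_VARIANTS[variant_draw[i]] if is_target[i]
                    else ps_drug[i].upper())
        demo_rows.append({
            "PRIMARYID": primaryid, "CASEID": caseid, "CASEVERSION": "1",
            "FDA_DT": _dt(fda),
            "AGE": str(int(rng.integers(20, 91))) if rng.random() < 0.3 else "",
            "AGE_COD": "YR",
            "SEX": ["M", "F", ""][sex_draw[i]],
            "OCCP_COD": occ_levels[occ_draw[i]],
            "REPORTER_COUNTRY": country_levels[country_draw[i]],
            "EVENT_DT": _dt(event_dt),
        })
        drug_rows.append({
            "PRIMARYID": primaryid, "CASEID": caseid, "DRUG_SEQ": "1",
            "ROLE_COD": "PS", "DRUGNAME": drugname,
            "PROD_AI": ps_drug[i].upper(),
        })
        ther_rows.append({
            "PRIMARYID": primaryid, "CASEID": caseid, "DSG_DRUG_SEQ": "1",
            "START_DT": start_str,
        })
        for k in range(int(n_concom[i])):
            concom = drugs[int(rng.integers(0, config.n_drugs))]
            drug_rows.append({
                "PRIMARYID": primaryid, "CASEID": caseid,
                "DRUG_SEQ": str(2 + k), "ROLE_COD": "C",
                "DRUGNAME": concom.upper(), "PROD_AI": concom.upper(),
            })
        reac_start, outc_start = len(reac_rows), len(outc_rows)
        for j in np.flatnonzero(hits[i]):
            reac_rows.append({"PRIMARYID": primaryid, "CASEID": caseid,
                              "PT": events[j]})
            if is_target[i]:
                truth_pair_counts[events[j]] = (
                    truth_pair_counts.get(events[j], 0) + 1)
        if outcome_levels[outcome_draw[i]]:
            outc_rows.append({"PRIMARYID": primaryid, "CASEID": caseid,
                              "OUTC_COD": outcome_levels[outcome_draw[i]]})

        if dup_flags[i]:
            # re-emit the case as a later version with a new primaryid
            dup_pid = caseid + "2"
            duplicate_map[caseid] = [primaryid, dup_pid]

            def _dup(rows: list[dict]) -> list[dict]:
                copies = []
                for row in rows:
                    c = dict(row)
                    c["PRIMARYID"] = dup_pid
                    if "CASEVERSION" in c:
                        c["CASEVERSION"] = "2"
                    copies.append(c)
                return copies

            demo_rows.extend(_dup(demo_rows[-1:]))
            drug_rows.extend(_dup(drug_rows[-(1 + int(n_concom[i])):]))
            ther_rows.extend(_dup(ther_rows[-1:]))
            reac_rows.extend(_dup(reac_rows[reac_start:]))
            outc_rows.extend(_dup(outc_rows[outc_start:]))

    span = f"{QUARTERS[0]}-{QUARTERS[-1]}"
    columns = {
        "DEMO": ["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "AGE",
                 "AGE_COD", "SEX", "OCCP_COD", "REPORTER_COUNTRY",
                 "EVENT_DT"],
        "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME",
                 "PROD_AI"],
        "REAC": ["PRIMARYID", "CASEID", "PT"],
        "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
        "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
    }
    tables = {
        kind: RawRecordSet(kind, span, columns[kind], rows)
        for kind, rows in (("DEMO", demo_rows), ("DRUG", drug_rows),
                           ("REAC", reac_rows), ("OUTC", outc_rows),
                           ("THER", ther_rows))
    }
    pt_soc_map = make_pt_soc_map(events, rng)
    ground_truth = {
        "seed": config.seed,
        "n_unique_cases": n,
        "n_target_reports": int(is_target.sum()),
        "duplicate_map": duplicate_map,
        "planted_signals": [list(s) for s in config.planted_signals],
        "target_pair_counts": truth_pair_counts,
        "n_negative_gaps": int(negative.sum()),
        "n_partial_start_dates": int(partial_start.sum()),
        "pt_soc_map": pt_soc_map,
        "synonyms": default_synonym_table(),
    }
    return tables, ground_truth


def split_by_quarter(tables: dict[str, RawRecordSet],
                     ) -> dict[str, dict[str, RawRecordSet]]:
    """Split whole-window record sets into per-quarter sets keyed by the
    quarter of each case's FDA receipt date."""
    quarter_by_pid = {row["PRIMARYID"]: quarter_of(row["FDA_DT"])
                      for row in tables["DEMO"].rows}
    out: dict[str, dict[str, RawRecordSet]] = {}
    for kind, recs in tables.items():
        for row in recs.rows:
            q = quarter_by_pid[row["PRIMARYID"]]
            qset = out.setdefault(q, {})
            if kind not in qset:
                qset[kind] = RawRecordSet(kind, q, list(recs.columns), [])
            qset[kind].rows.append(row)
    # every quarter gets all five files, even if empty
    for q, qset in out.items():
        for kind, recs in tables.items():
            if kind not in qset:
                qset[kind] = RawRecordSet(kind, q, list(recs.columns), [])
    return out


def write_corpus(tables: dict[str, RawRecordSet], ground_truth: dict,
                 directory: Path | str) -> list[str]:
    """Write quarterly FAERS files plus ground truth and mapping files.

    Emits DEMO/DRUG/REAC/OUTC/THER per quarter, ``ground_truth.json``,
    ``synonyms.txt`` (variant<TAB>canonical) and ``pt_soc.txt``
    (PT<TAB>SOC).  Returns the sorted quarter labels written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_quarter = split_by_quarter(tables)
    for qset in by_quarter.values():
        write_quarter(qset, directory)
    (directory / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=1, sort_keys=True), encoding="utf-8")
    (directory / "synonyms.txt").write_text(
        "".join(f"{k}\t{v}\n"
                for k, v in ground_truth["synonyms"].items()),
        encoding="utf-8")
    (directory / "pt_soc.txt").write_text(
        "".join(f"{k}\t{v}\n"
                for k, v in sorted(ground_truth["pt_soc_map"].items())),
        encoding="utf-8")
    return sorted(by_quarter)
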