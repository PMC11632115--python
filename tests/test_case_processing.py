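"""Deduplication, drug-name standardization, suspect selection, the PT
minimum-count filter, and PT -> SOC mapping."""

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.case_processing import (DrugEventPair, SafetyReport, NO_MATCH,
                                      apply_min_count_filter,
                                      build_drug_event_pairs, deduplicate,
                                      map_to_soc, normalize_drug_name,
                                      select_suspect_reports,
                                      standardize_drug)
from pvsignal.faers_io import RawRecordSet


def report(primaryid, caseid, version=1, fda_date="20200101"):
    return SafetyReport(primaryid=primaryid, caseid=caseid,
                        caseversion=version, fda_date=fda_date)


class TestDeduplicate:
    def test_highest_version_retained(self):
        v1 = report("7771", "777", 1)
        v2 = report("7772", "777", 2)
        assert deduplicate([v1, v2]) == [v2]
        assert deduplicate([v2, v1]) == [v2]

    def test_single_version_is_identity(self):
        reports = [report("1", "a"), report("2", "b")]
        assert deduplicate(reports) == sorted(reports,
                                              key=lambda r: r.caseid)

    def test_later_fda_date_wins_at_equal_version(self):
        early = report("9001", "900", 1, "20200101")
        late = report("9002", "900", 1, "20210101")
        # brute-force max over the (fda_date, version, primaryid) key
        expected = max([early, late], key=lambda r: (r.fda_date,
                                                     r.caseversion,
                                                     r.primaryid))
        assert deduplicate([early, late]) == [expected] == [late]

    def test_missing_caseid_kept_with_warning(self):
        orphan = report("5551", "")
        with pytest.warns(UserWarning, match="no caseid"):
            result = deduplicate([orphan, report("1", "a")])
        assert orphan in result

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 20), st.integers(1, 3),
                              st.sampled_from(["20200101", "20210615"]))))
    def test_idempotent_and_order_invariant(self, specs):
        reports = [report(f"{cid}{v}", str(cid), v, dt)
                   for cid, v, dt in specs]
        once = deduplicate(reports)
        assert deduplicate(once) == once
        assert deduplicate(list(reversed(reports))) == once
        assert len({r.caseid for r in once}) == len(once)


class TestStandardizeDrug:
    SYNONYMS = {"poteligeo": "mogamulizumab",
                "mogamulizumab": "mogamulizumab"}

    def test_brand_name_lookup(self):
        assert standardize_drug("POTELIGEO", self.SYNONYMS) == "mogamulizumab"

    def test_biologic_suffix_stripped(self):
        assert standardize_drug("Mogamulizumab-kpkc",
                                self.SYNONYMS) == "mogamulizumab"
        assert normalize_drug_name("Mogamulizumab-kpkc") == "mogamulizumab"

    def test_punctuation_and_case_normalized(self):
        assert normalize_drug_name("  MOGAMULIZUMAB.  ") == "mogamulizumab"

    def test_unmatched_name_flagged(self):
        assert standardize_drug("aspirin", self.SYNONYMS) == NO_MATCH


def drug_row(pid, role, name, seq="1"):
    return {"PRIMARYID": pid, "DRUG_SEQ": seq, "ROLE_COD": role,
            "DRUGNAME": name, "STANDARDIZED": name}


class TestSelectSuspectReports:
    def test_secondary_suspect_excluded_under_ps_only(self):
        reports = [report("1", "a")]
        rows = [drug_row("1", "SS", "mogamulizumab")]
        assert select_suspect_reports(reports, rows, "mogamulizumab") == []
        assert select_suspect_reports(reports, rows, "mogamulizumab",
                                      "PS_and_SS") == reports

    def test_drug_listed_twice_selected_once(self):
        reports = [report("1", "a")]
        rows = [drug_row("1", "PS", "mogamulizumab", "1"),
                drug_row("1", "C", "mogamulizumab", "2")]
        assert select_suspect_reports(reports, rows,
                                      "mogamulizumab") == reports

    def test_counts_match_brute_force_scan(self):
        reports = [report(str(i), f"c{i}") for i in range(10)]
        rows = [drug_row(str(i), "PS",
                         "mogamulizumab" if i < 4 else "other")
                for i in range(10)]
        selected = select_suspect_reports(reports, rows, "mogamulizumab")
        brute = [r for r in reports
                 if any(row["PRIMARYID"] == r.primaryid
                        and row["ROLE_COD"] == "PS"
                        and row["STANDARDIZED"] == "mogamulizumab"
                        for row in rows)]
        assert selected == brute and len(selected) == 4


def pair(pid, pt, drug="mogamulizumab"):
    return DrugEventPair(primaryid=pid, drug_id=drug, pt_name=pt)


class TestMinCountFilter:
    def test_boundary_two_dropped_three_retained(self):
        pairs = ([pair(str(i), "Rare") for i in range(2)]
                 + [pair(str(i), "Common") for i in range(3)])
        kept, dropped = apply_min_count_filter(pairs, min_count=3)
        assert {p.pt_name for p in kept} == {"Common"}
        assert dropped == {"Rare": 2}

    def test_min_count_one_is_identity(self):
        pairs = [pair("1", "Anything")]
        kept, dropped = apply_min_count_filter(pairs, min_count=1)
        assert kept == pairs and dropped == {}

    def test_distinct_reports_counted_not_rows(self):
        # same report twice for one PT counts once
        pairs = [pair("1", "Rash"), pair("1", "Rash"), pair("2", "Rash")]
        _, dropped = apply_min_count_filter(pairs, min_count=3)
        assert dropped == {"Rash": 2}

    def test_invalid_min_count_rejected(self):
        with pytest.raises(ValueError):
            apply_min_count_filter([], min_count=0)


class TestMapToSoc:
    MAP = {"Rash": "Skin and subcutaneous tissue disorders",
           "Pyrexia": "General disorders and administration site conditions"}

    def test_lookup(self):
        mapped, log = map_to_soc([pair("1", "Rash")], self.MAP)
        assert mapped[0].soc_name == "Skin and subcutaneous tissue disorders"
        assert log["mapped"] == 1

    def test_unmapped_policies(self):
        pairs = [pair("1", "Vertigo")]
        dropped, log = map_to_soc(pairs, self.MAP, "drop")
        assert dropped == [] and log["unmapped"] == 1
        kept, _ = map_to_soc(pairs, self.MAP, "keep_flagged")
        assert kept[0].soc_name == "<unmapped>"

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            map_to_soc([pair("1", "Rash")], {})

    def test_soc_counts_sum_over_member_pts(self):
        # 5 PTs across 2 SOCs: SOC pair counts = sum of member PT counts
        soc_map = {f"PT{i}": ("SocA" if i < 3 else "SocB") for i in range(5)}
        pairs = [pair(f"{i}{j}", f"PT{i}")
                 for i in range(5) for j in range(i + 1)]
        mapped, _ = map_to_soc(pairs, soc_map)
        by_soc = {}
        for p in mapped:
            by_soc[p.soc_name] = by_soc.get(p.soc_name, 0) + 1
        assert by_soc == {"SocA": 1 + 2 + 3, "SocB": 4 + 5}
        assert sum(by_soc.values()) == len(pairs)


def test_build_pairs_unique_per_report_drug_pt():
    reac = RawRecordSet("REAC", "2020Q1", ["PRIMARYID", "CASEID", "PT"], [
        {"PRIMARYID": "1", "CASEID": "1", "PT": "Rash"},
        {"PRIMARYID": "1", "CASEID": "1", "PT": "Rash"},   # duplicate row
        {"PRIMARYID": "1", "CASEID": "1", "PT": " Fever "},
        {"PRIMARYID": "2", "CASEID": "2", "PT": "Rash"},
    ])
    suspect = {"1": {"drugA"}, "2": {"drugB"}}
    pairs = build_drug_event_pairs(reac, suspect)
    assert len(pairs) == 3
    assert {(p.primaryid, p.drug_id, p.pt_name) for p in pairs} == {
        ("1", "drugA", "Rash"), ("1", "drugA", "Fever"),
        ("2", "drugB", "Rash")}
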