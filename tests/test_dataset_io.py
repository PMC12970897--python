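"""Parsing, deduplication, drug-name normalization and report selection."""

import numpy as np
import pandas as pd
import pytest

from pvsignal import (
    DrugDictionary,
    ParseError,
    SRSDataset,
    deduplicate,
    default_drug_dictionary,
    generate,
    normalize_drugs,
    normalize_name,
    read_dataset,
    read_srs,
    select_reports,
    write_dataset,
    write_faers,
)
from conftest import EGPA, small_config, write_faers_fixture


class TestFaersParsing:
    def test_row_counts_preserved(self, tmp_path):
        d = write_faers_fixture(
            tmp_path,
            demo_rows=[
                {"primaryid": "100", "caseid": "1", "fda_dt": "20240101", "age": "45",
                 "age_cod": "YR", "sex": "F", "wt": "70", "wt_cod": "KG"},
                {"primaryid": "200", "caseid": "2", "fda_dt": "20240102", "age": "600",
                 "age_cod": "MON", "sex": "M", "wt": "154", "wt_cod": "LBS"},
            ],
            drug_rows=[
                {"primaryid": "100", "drug_seq": "1", "role_cod": "PS", "drugname": "SINGULAIR"},
                {"primaryid": "200", "drug_seq": "1", "role_cod": "C", "drugname": "ASPIRIN"},
            ],
            reac_rows=[
                {"primaryid": "100", "pt": EGPA},
                {"primaryid": "200", "pt": "Headache"},
            ],
        )
        ds = read_srs(d, "faers")
        assert ds.n_reports == 2
        assert len(ds.drugs) == 2 and len(ds.events) == 2
        # unit conversions
        by_id = ds.cases.set_index("report_id")
        assert by_id.loc["200", "age"] == pytest.approx(50.0)
        assert by_id.loc["200", "weight"] == pytest.approx(154 * 0.453592)
        assert by_id.loc["100", "sex"] == "female"

    def test_missing_mandatory_column_names_file_and_column(self, tmp_path):
        d = write_faers_fixture(
            tmp_path,
            demo_rows=[{"primaryid": "1", "caseid": "1"}],
            drug_rows=[{"primaryid": "1", "drugname": "X"}],  # role_cod missing
            reac_rows=[{"primaryid": "1", "pt": "Rash"}],
        )
        with pytest.raises(ParseError, match="role_cod"):
            read_srs(d, "faers")

    def test_unparseable_date_nulled_and_counted(self, tmp_path):
        d = write_faers_fixture(
            tmp_path,
            demo_rows=[{"primaryid": "1", "caseid": "1", "fda_dt": "20240101"}],
            drug_rows=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "X"}],
            reac_rows=[{"primaryid": "1", "pt": "Rash", "onset_dt": "20249999"}],
        )
        ds = read_srs(d, "faers")
        assert ds.events["onset_date"].isna().all()
        assert ds.parse_warnings.get("unparseable_dates:REAC.onset_dt") == 1

    def test_partial_date_imputed_to_first_and_flagged(self, tmp_path):
        d = write_faers_fixture(
            tmp_path,
            demo_rows=[{"primaryid": "1", "caseid": "1", "fda_dt": "20240101"}],
            drug_rows=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "X"}],
            reac_rows=[{"primaryid": "1", "pt": "Rash", "onset_dt": "202403"}],
        )
        ds = read_srs(d, "faers")
        assert ds.events.loc[0, "onset_date"] == pd.Timestamp("2024-03-01")
        assert bool(ds.events.loc[0, "onset_date_imputed"])


class TestJaderCvarParsing:
    def test_jader_duplicate_drug_row_removed_on_dedup(self, tmp_path):
        (tmp_path / "demo.csv").write_text("caseid,sex,age\nJ1,F,50\n")
        (tmp_path / "drug.csv").write_text(
            "caseid,drugname,role\nJ1,pranlukast,suspect\nJ1,pranlukast,suspect\n"
        )
        (tmp_path / "reac.csv").write_text(f"caseid,pt\nJ1,{EGPA}\n")
        ds = read_srs(tmp_path, "jader")
        assert len(ds.drugs) == 2
        ds, report = deduplicate(ds)
        assert len(ds.drugs) == 1
        assert report.n_drug_rows_removed == 1

    def test_cvar_orphan_drug_rows_error_lists_ids(self, tmp_path):
        (tmp_path / "reports.csv").write_text("report_id,sex\nC1,M\n")
        (tmp_path / "report_drug.csv").write_text(
            "report_id,drugname,role\nC1,montelukast,suspect\nC9,montelukast,suspect\n"
        )
        (tmp_path / "reactions.csv").write_text(f"report_id,pt\nC1,{EGPA}\n")
        with pytest.raises(ParseError, match="C9"):
            read_srs(tmp_path, "cvar")


class TestDeduplicate:
    def _two_versions(self):
        cases = pd.DataFrame(
            {
                "report_id": ["100", "101"],
                "case_id": ["1", "1"],
                "version_key": ["20230101:100", "20240101:101"],
                "age": [50.0, 50.0],
                "sex": ["female", "female"],
                "weight": [np.nan, np.nan],
                "event_year": pd.array([2023, 2023], dtype="Int64"),
                "country": ["US", "US"],
                "reporter": ["physician", "physician"],
                "outcomes": ["other", "other"],
            }
        )
        drugs = pd.DataFrame(
            {
                "report_id": ["100", "101"],
                "verbatim_name": ["montelukast", "montelukast"],
                "ingredient": [None, None],
                "role": ["PS", "PS"],
                "start_date": [pd.NaT, pd.NaT],
                "start_date_imputed": [False, False],
                "indication_pt": [None, None],
            }
        )
        events = pd.DataFrame(
            {
                "report_id": ["100", "101"],
                "pt": [EGPA, EGPA],
                "onset_date": [pd.NaT, pd.NaT],
                "onset_date_imputed": [False, False],
            }
        )
        return SRSDataset("FAERS", cases, drugs, events)

    def test_keeps_latest_version_per_case(self):
        ds, report = deduplicate(self._two_versions())
        assert set(ds.cases["report_id"]) == {"101"}
        assert report.n_cases_removed == 1
        # linked tables follow
        assert set(ds.drugs["report_id"]) == {"101"}

    def test_idempotent_and_zero_on_clean_data(self):
        ds1, _ = deduplicate(self._two_versions())
        ds2, report2 = deduplicate(ds1)
        assert report2.n_cases_removed == 0
        assert ds2.equals(ds1)

    def test_injected_duplicate_count_recovered(self):
        cfg = small_config(n_reports=4000, duplicate_rate=0.05, seed=3)
        ds, truth = generate(cfg)
        deduped, report = deduplicate(ds)
        assert truth["n_duplicates"] == 200
        assert report.n_cases_removed == truth["n_duplicates"]
        assert deduped.n_reports == 4000


class TestNormalizeDrugs:
    def test_trade_name_and_whitespace_and_miss(self):
        d = default_drug_dictionary()
        assert d.lookup("SINGULAIR") == "montelukast"
        assert d.lookup("montelukast ") == "montelukast"
        assert d.lookup("aspirin") is None

    def test_normalization_is_nfkc_casefold(self):
        assert normalize_name("  Ｍontelukast  Sodium ") == "montelukast sodium"

    def test_records_without_match_are_retained(self):
        ds, _ = generate(small_config(n_reports=200, seed=1))
        ds.drugs.loc[0, "verbatim_name"] = "completely unknown drug"
        ds.drugs["ingredient"] = None
        out = normalize_drugs(ds, default_drug_dictionary())
        assert len(out.drugs) == len(ds.drugs)
        assert out.drugs.loc[0, "ingredient"] is None

    def test_dictionary_from_csv(self, tmp_path):
        p = tmp_path / "dict.csv"
        p.write_text("name,ingredient\nSINGULAIR,montelukast\nACCOLATE,zafirlukast\n")
        d = DrugDictionary.from_csv(p)
        assert d.lookup("singulair") == "montelukast"
        assert d.lookup("zafirlukast") == "zafirlukast"  # ingredient maps to itself


class TestSelectReports:
    def test_single_report_all_sets(self, planted_dataset):
        ds, _ = planted_dataset
        exposed, with_event, both = select_reports(
            ds, ["montelukast"], roles={"PS", "concomitant"}, event_pts=[EGPA]
        )
        assert both == exposed & with_event

    def test_role_filter_excludes_concomitant_only(self):
        ds, _ = generate(small_config(n_reports=3000, seed=5))
        exposed_ps, _, _ = select_reports(ds, ["montelukast"], roles={"PS"}, event_pts=[EGPA])
        conc = ds.drugs[
            (ds.drugs["ingredient"] == "montelukast") & (ds.drugs["role"] == "concomitant")
        ]["report_id"]
        ps = ds.drugs[
            (ds.drugs["ingredient"] == "montelukast") & (ds.drugs["role"] == "PS")
        ]["report_id"]
        conc_only = set(conc) - set(ps)
        assert conc_only, "fixture should contain concomitant-only exposures"
        assert not (exposed_ps & conc_only)

    def test_counts_match_exhaustive_scan(self, planted_dataset):
        ds, _ = planted_dataset
        roles = {"PS"}
        exposed, with_event, both = select_reports(ds, ["montelukast"], roles, [EGPA])
        # brute force: row-by-row scan
        exp = set()
        for _, row in ds.drugs.iterrows():
            if row["ingredient"] == "montelukast" and row["role"] in roles:
                exp.add(row["report_id"])
        evt = set()
        for _, row in ds.events.iterrows():
            if normalize_name(row["pt"]) == normalize_name(EGPA):
                evt.add(row["report_id"])
        assert exposed == exp and with_event == evt and both == exp & evt

    def test_invariant_to_row_duplication(self, planted_dataset):
        ds, _ = planted_dataset
        dup = ds.copy()
        dup.drugs = pd.concat([dup.drugs, dup.drugs.head(500)], ignore_index=True)
        dup.events = pd.concat([dup.events, dup.events.head(500)], ignore_index=True)
        assert select_reports(dup, ["montelukast"], {"PS"}, [EGPA]) == select_reports(
            ds, ["montelukast"], {"PS"}, [EGPA]
        )

    def test_empty_ingredients_error(self, planted_dataset):
        ds, _ = planted_dataset
        with pytest.raises(ValueError, match="empty ingredient"):
            select_reports(ds, [], {"PS"}, [EGPA])


class TestRoundTrip:
    def test_canonical_format_round_trip(self, tmp_path):
        ds, _ = generate(small_config(n_reports=500, seed=9))
        write_dataset(ds, tmp_path / "canon")
        back = read_dataset(tmp_path / "canon")
        assert back.dialect == ds.dialect
        assert back.n_reports == ds.n_reports
        pd.testing.assert_frame_equal(
            back.drugs.sort_values(["report_id", "verbatim_name"]).reset_index(drop=True),
            ds.drugs.sort_values(["report_id", "verbatim_name"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_faers_writer_output_is_parseable_and_equivalent(self, tmp_path):
        ds, _ = generate(small_config(n_reports=800, seed=13))
        write_faers(ds, tmp_path / "faers")
        back = read_srs(tmp_path / "faers", "synthetic")
        assert back.n_reports == ds.n_reports
        q1 = select_reports(ds, ["montelukast"], {"PS"}, [EGPA])
        q2 = select_reports(back, ["montelukast"], {"PS"}, [EGPA])
        # ingredient column is only set after normalization on re-read
        back_norm = normalize_drugs(back, default_drug_dictionary())
        q2 = select_reports(back_norm, ["montelukast"], {"PS"}, [EGPA])
        assert [len(s) for s in q1] == [len(s) for s in q2]
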