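"""Parsing, deduplication, suspect matching and case assembly."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal import (
    SchemaError,
    SimulationConfig,
    assemble_cases,
    deduplicate,
    filter_by_age,
    generate,
    match_primary_suspect,
    parse_faers_date,
    parse_faers_table,
)
from pvsignal.faers_io import CaseReport, target_caseids


def _demo(rows):
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    text = "primaryid$caseid$fda_dt\n" + "\n".join("$".join(r) for r in rows) + "\n"
    return parse_faers_table(text, "demo")


class TestParsing:
    def test_typed_demo_row(self):
        df = parse_faers_table("primaryid$caseid$fda_dt\n1$100$20200315\n", "demo")
        assert len(df) == 1
        assert df.loc[0, "fda_dt"] == pd.Timestamp("2020-03-15")

    def test_partial_date_is_null_but_row_retained(self):
        df = parse_faers_table("primaryid$caseid$fda_dt\n1$100$202003\n", "demo")
        assert len(df) == 1
        assert pd.isna(df.loc[0, "fda_dt"])

    def test_missing_required_column_names_it(self):
        with pytest.raises(SchemaError, match="fda_dt"):
            parse_faers_table("primaryid$caseid\n1$100\n", "demo")

    def test_empty_stream_gives_empty_collection(self):
        assert parse_faers_table("", "reac").empty

    def test_unknown_columns_preserved(self):
        df = parse_faers_table(
            "primaryid$caseid$fda_dt$mystery\n1$100$20200315$keepme\n", "demo"
        )
        assert df.loc[0, "mystery"] == "keepme"

    @pytest.mark.parametrize(
        "age, cod, expected",
        [("50", "YR", 50.0), ("24", "MON", 2.0), ("5", "DEC", 50.0), ("7", "XX", None)],
    )
    def test_age_unit_conversion(self, age, cod, expected):
        df = parse_faers_table(
            f"primaryid$caseid$fda_dt$age$age_cod\n1$100$20200315${age}${cod}\n", "demo"
        )
        got = df.loc[0, "age_years"]
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == pytest.approx(expected, abs=0.1)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("20200131", dt.date(2020, 1, 31)),
        ("202001", None),  # partial YYYYMM
        ("2020", None),  # partial YYYY
        ("20200230", None),  # invalid calendar day
        ("", None),
        ("2020013a", None),
        (" 20200131 ", dt.date(2020, 1, 31)),
    ],
)
def test_parse_faers_date(raw, expected):
    assert parse_faers_date(raw) == expected


@given(st.text(max_size=12))
def test_parse_faers_date_is_total(s):
    out = parse_faers_date(s)
    assert out is None or isinstance(out, dt.date)


class TestDeduplicate:
    def test_keeps_highest_fda_dt(self):
        df = _demo([("A", "1", "20200101"), ("B", "1", "20200301")])
        kept = deduplicate(df)
        assert kept["primaryid"].tolist() == ["B"]

    def test_fda_dt_tie_broken_by_numeric_primaryid(self):
        df = _demo([("3", "1", "20200301"), ("10", "1", "20200301")])
        assert deduplicate(df)["primaryid"].tolist() == ["10"]

    def test_null_fda_dt_sorts_lowest(self):
        df = _demo([("B", "1", "202003"), ("A", "1", "20190101")])
        assert deduplicate(df)["primaryid"].tolist() == ["A"]

    def test_output_ascending_by_caseid(self):
        df = _demo([("X", "2", "20200101"), ("Y", "1", "20200101")])
        assert deduplicate(df)["caseid"].tolist() == ["1", "2"]

    def test_idempotent_and_never_grows_on_synthetic_data(self, small_tables):
        demo = parse_faers_table(_as_text(small_tables.demo), "demo")
        once = deduplicate(demo)
        twice = deduplicate(once)
        assert len(once) <= len(demo)
        pd.testing.assert_frame_equal(once, twice)

    def test_recovers_generated_ground_truth(self):
        t = generate(SimulationConfig(n_reports=500, seed=3, duplicate_rate=0.5))
        kept = deduplicate(parse_faers_table(_as_text(t.demo), "demo"))
        assert sorted(kept["primaryid"]) == sorted(t.truth["primaryid"])


def _as_text(df):
    return "$".join(df.columns) + "\n" + "\n".join(
        "$".join(map(str, r)) for r in df.itertuples(index=False, name=None)
    ) + "\n"


class TestSuspectMatching:
    def _drug(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "caseid", "drugname", "role_cod"])

    def test_normalized_whole_field_match(self):
        df = self._drug([("1", "1", "  elmiron  ", "PS")])
        assert match_primary_suspect(df, ["ELMIRON"]) == {"1"}

    def test_concomitant_role_not_matched(self):
        df = self._drug([("1", "1", "ELMIRON", "C")])
        assert match_primary_suspect(df, ["ELMIRON"]) == set()

    def test_partial_name_not_matched(self):
        df = self._drug([("1", "1", "ELMIRON PLUS OTHER", "PS")])
        assert match_primary_suspect(df, ["ELMIRON"]) == set()

    def test_empty_synonyms_rejected(self):
        with pytest.raises(ValueError):
            match_primary_suspect(self._drug([]), [])

    def test_matched_set_equals_generator_ground_truth(self, small_tables, small_config):
        cases = assemble_cases(small_tables, restrict=False)
        ids = target_caseids(cases, [small_config.target_drug])
        truth = small_tables.truth
        expected = set(truth.loc[truth["drug"] == small_config.target_drug, "caseid"])
        assert ids == expected


class TestAssembleCases:
    def test_duplicates_collapse_to_one_case_each(self):
        cfg = SimulationConfig(
            n_reports=200,
            seed=5,
            duplicate_rate=0.5,
            drug_names=[SimulationConfig().target_drug],
        )
        cases = assemble_cases(generate(cfg))
        assert len(cases) == 200
        assert len({c.caseid for c in cases}) == 200

    def test_earliest_therapy_start_wins(self):
        demo = parse_faers_table("primaryid$caseid$fda_dt\n1$1$20200315\n", "demo")
        drug = pd.DataFrame(
            [("1", "1", "1", "ELMIRON", "PS"), ("1", "1", "2", "ELMIRON", "PS")],
            columns=["primaryid", "caseid", "drug_seq", "drugname", "role_cod"],
        )
        reac = pd.DataFrame([("1", "1", "Nausea")], columns=["primaryid", "caseid", "pt"])
        ther = parse_faers_table(
            "primaryid$caseid$dsg_drug_seq$start_dt\n"
            "1$1$1$20190101\n1$1$2$20180601\n",
            "ther",
        )
        outc = pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"])
        cases = assemble_cases(
            {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc},
            ["ELMIRON"],
        )
        assert cases[0].therapy_starts["elmiron"] == dt.date(2018, 6, 1)

    def test_pt_sets_match_generated_ground_truth(self, small_tables, universe):
        cases, _ = universe
        truth = small_tables.truth.set_index("caseid")
        for case in cases:
            assert case.pts == frozenset(truth.loc[case.caseid, "pts"])

    def test_caseids_unique(self, universe):
        cases, _ = universe
        ids = [c.caseid for c in cases]
        assert len(ids) == len(set(ids))

    def test_duplicate_reac_rows_collapse_to_one_pt(self):
        demo = parse_faers_table("primaryid$caseid$fda_dt\n1$1$20200315\n", "demo")
        drug = pd.DataFrame(
            [("1", "1", "ELMIRON", "PS")],
            columns=["primaryid", "caseid", "drugname", "role_cod"],
        )
        reac = pd.DataFrame(
            [("1", "1", "Nausea"), ("1", "1", "Nausea")],
            columns=["primaryid", "caseid", "pt"],
        )
        cases = assemble_cases({"demo": demo, "drug": drug, "reac": reac}, ["ELMIRON"])
        assert cases[0].pts == frozenset({"Nausea"})


class TestAgeFilter:
    def _case(self, age):
        return CaseReport(
            primaryid="1", caseid="1", fda_dt=None, event_dt=None, sex="female",
            age_years=age, reporter="consumer", country="US", pts=frozenset({"X"}),
        )

    def test_minimum_age_excludes_minors_and_missing(self):
        cases = [self._case(a) for a in (15, 16, None)]
        kept = filter_by_age(cases, 16)
        assert [c.age_years for c in kept] == [16]

    def test_zero_threshold_keeps_all_documented(self):
        cases = [self._case(a) for a in (1, 30, 99)]
        assert filter_by_age(cases, 0) == cases

    def test_count_matches_bruteforce_on_synthetic_cohort(self, universe):
        cases, _ = universe
        kept = filter_by_age(cases, 16)
        expected = sum(1 for c in cases if c.age_years is not None and c.age_years >= 16)
        assert len(kept) == expected
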