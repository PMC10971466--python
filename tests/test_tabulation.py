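"""Normalized-frequency, onset-day and age-of-onset tables."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from vaersvasc import tabulation as tab
from vaersvasc import reference_tables
from vaersvasc.case_extraction import KD, KD_MIS_COMPOSITE, VASCULITIS, extract_cases


class TestNormalizedFrequency:
    @pytest.mark.parametrize(
        "count,denom,convention,expected",
        [
            (91, 2790, tab.ROUND_NEAREST, 3262),
            (5, 241, tab.ROUND_NEAREST, 2075),
            (11, 21679, tab.ROUND_NEAREST, 51),
            (3, 851, tab.TRUNCATE, 352),
            (19, 2117, tab.TRUNCATE, 897),
            (0, 12456, tab.TRUNCATE, "<8"),
            (0, 16084, tab.ROUND_NEAREST, "<6"),
            (0, 100000, tab.TRUNCATE, "<1"),
        ],
    )
    def test_published_cells_and_bounds(self, count, denom, convention, expected):
        assert tab.normalized_frequency(count, denom, convention) == expected

    def test_half_cases_separate_the_conventions(self):
        # 1/851 -> 117.51...: truncate 117, round 118
        assert tab.normalized_frequency(1, 851, tab.TRUNCATE) == 117
        assert tab.normalized_frequency(1, 851, tab.ROUND_NEAREST) == 118

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            tab.normalized_frequency(1, 0)
        with pytest.raises(ValueError):
            tab.normalized_frequency(-1, 10)

    @given(
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=1000),
    )
    def test_unrounded_frequency_is_scale_free(self, count, denom, k):
        assert Fraction(100000 * count, denom) == Fraction(100000 * count * k, denom * k)

    @given(
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=10**6),
    )
    def test_truncate_never_exceeds_round_nearest(self, count, denom):
        assert tab.normalized_frequency(count, denom, tab.TRUNCATE) <= tab.normalized_frequency(
            count, denom, tab.ROUND_NEAREST
        )


class TestPublishedConventionAudit:
    def test_per_vaccine_table_matches_round_half_away_everywhere(self):
        table = reference_tables.kd_vaccine_frequency_table()
        for _, row in table.iterrows():
            assert (
                tab.normalized_frequency(
                    row["case_count"], row["denominator"], tab.ROUND_NEAREST
                )
                == row["frequency_per_100k"]
            ), row["vaccine_code"]

    def test_per_age_table_matches_truncation_except_known_age29_cell(self):
        # the published per-age table truncates everywhere except its age-29
        # cell (1/14,700 -> 6.80, printed 7), which matches round-half-away:
        # a one-cell internal inconsistency of the source table.
        table = reference_tables.covid_age_frequency_table()
        mismatches = []
        for _, row in table.iterrows():
            got = tab.normalized_frequency(
                row["case_count"], row["denominator"], tab.TRUNCATE
            )
            if got != row["frequency_per_100k"]:
                mismatches.append(int(row["age"]))
        assert mismatches == [29]
        age29 = table[table["age"] == 29].iloc[0]
        assert (
            tab.normalized_frequency(
                age29["case_count"], age29["denominator"], tab.ROUND_NEAREST
            )
            == age29["frequency_per_100k"]
        )


class TestVaccineFrequencyTable:
    def test_fixture_counts_with_child_denominator_window(
        self, fixture_reports, fixture_cases
    ):
        table = tab.vaccine_frequency_table(
            fixture_reports, fixture_cases, KD, min_cases=0,
            denominator_age_window=(0, 5),
        ).set_index("vaccine_code")
        assert table.loc["MENB", "case_count"] == 2
        assert table.loc["MENB", "denominator"] == 3
        # the multi-vaccine KD report contributes to both its codes
        assert table.loc["HIBV", "case_count"] == 1
        assert table.loc["PNC13", "case_count"] == 1
        # missing-age and out-of-window reports fall outside the denominator,
        # so their codes drop out entirely when the denominator is empty
        assert "UNK" not in table.index
        assert "MMR" not in table.index

    def test_min_cases_threshold_excludes_sparse_vaccines(
        self, fixture_reports, fixture_cases
    ):
        table = tab.vaccine_frequency_table(
            fixture_reports, fixture_cases, KD, min_cases=5,
            denominator_age_window=None,
        )
        assert table.empty

    def test_cohort_counts_match_sidecar_truth(self, cohort):
        cases = extract_cases(cohort["reports"])
        table = tab.vaccine_frequency_table(
            cohort["reports"], cases, cohort["truth"].case_category,
            min_cases=0, denominator_age_window=None,
        ).set_index("vaccine_code")
        for code, entry in cohort["truth"].per_vaccine.items():
            assert table.loc[code, "case_count"] == entry["cases"]
            assert table.loc[code, "denominator"] == entry["denominator"]


class TestOnsetTable:
    def test_fixture_blank_and_day_rows(self, fixture_reports, fixture_cases):
        table = tab.onset_table(
            fixture_reports, fixture_cases, KD, ["MENB", "HIBV", "PNC13"]
        )
        assert table.loc[tab.BLANK, "PNC13"] == 1
        assert table.loc[0, "MENB"] == 1
        assert table.loc[0, "HIBV"] == 1
        assert table.loc[2, "MENB"] == 1
        assert table["MENB"].sum() == 2

    def test_no_flagged_reports_gives_all_zero_rows(
        self, fixture_reports, fixture_cases
    ):
        table = tab.onset_table(fixture_reports, fixture_cases, "MIS", ["MENB"])
        assert (table == 0).all().all()
        assert list(table.index) == [tab.BLANK] + list(range(31))

    def test_cohort_column_sums_match_truth(self, cohort):
        truth = cohort["truth"]
        cases = extract_cases(cohort["reports"])
        codes = sorted(truth.per_vaccine)
        table = tab.onset_table(
            cohort["reports"], cases, truth.case_category, codes, max_day=30
        )
        for code in codes:
            expected = sum(
                1
                for info in truth.reports.values()
                if info["categories"][truth.case_category]
                and code in info["vaccine_codes"]
            )
            assert table[code].sum() == expected


class TestAgeTable:
    def test_fixture_floor_binning_and_na_row(self, fixture_reports, fixture_cases):
        table = tab.age_table(fixture_reports, fixture_cases, [KD, VASCULITIS])
        assert table.loc[0, KD] == 1  # age 0.5 bins to 0
        assert table.loc[1, KD] == 1
        assert table.loc[3, KD] == 1
        assert table.loc[tab.NA_AGE, VASCULITIS] == 1  # missing age
        assert table.loc[17, VASCULITIS] == 1

    def test_conservation_with_wide_age_range(self, cohort):
        truth = cohort["truth"]
        cases = extract_cases(cohort["reports"])
        category = truth.case_category
        table = tab.age_table(cohort["reports"], cases, [category], max_age=120)
        assert table[category].sum() == cases[category].sum()


class TestAgeFrequencyTable:
    def test_fixture_covid_rows(self, fixture_reports, fixture_cases):
        table = tab.age_frequency_table(
            fixture_reports, fixture_cases, KD_MIS_COMPOSITE, "COVID19",
            age_range=(1, 30),
        ).set_index("age")
        assert table.loc[8, "case_count"] == 1
        assert table.loc[8, "denominator"] == 1
        assert table.loc[8, "frequency_per_100k"] == 100000
        # symptomful non-case at 17 -> zero-count bound
        assert table.loc[17, "frequency_per_100k"] == "<100000"
        # the zero-symptom report at 30 is outside the denominator
        assert table.loc[30, "denominator"] == 0
        assert table.loc[30, "frequency_per_100k"] is None

    def test_conservation_against_truth(self, cohort):
        truth = cohort["truth"]
        cases = extract_cases(cohort["reports"])
        table = tab.age_frequency_table(
            cohort["reports"], cases, truth.case_category, "COVID19",
            age_range=(0, 120),
        )
        expected = sum(
            1
            for info in truth.reports.values()
            if info["categories"][truth.case_category]
            and "COVID19" in info["vaccine_codes"]
            and info["age"] is not None
            and info["symptom_terms"]
        )
        assert table["case_count"].sum() == expected


class TestWriters:
    def test_csv_and_text_preserve_markers(self, tmp_path, fixture_reports, fixture_cases):
        table = tab.age_frequency_table(
            fixture_reports, fixture_cases, KD_MIS_COMPOSITE, "COVID19"
        )
        csv_path, txt_path = tmp_path / "t.csv", tmp_path / "t.txt"
        tab.write_table_csv(table, csv_path)
        tab.write_table_text(table, txt_path)
        assert "<100000" in csv_path.read_text()
        assert "<100000" in txt_path.read_text()
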