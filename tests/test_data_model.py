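"""Metabolite table I/O, aglycone aggregation and phase-II ratio phenotyping."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabotyper import data_model as dm


def _write(tmp_path, df, name="t.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def _table_df(values: np.ndarray) -> pd.DataFrame:
    n = len(values)
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "subject_id": [f"P{i // 2}" for i in range(n)],
            "study": ["acute"] * n,
            "condition": ["716"] * n,
        }
    )
    vals = pd.DataFrame(values, columns=dm.METABOLITE_NAMES_11)
    return pd.concat([meta, vals], axis=1)


class TestReader:
    def test_reads_cohort_shape(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        dm.write_metabolite_table(cohort.table, path)
        back = dm.read_metabolite_table(path)
        assert back.n_samples == 83
        assert back.n_variables == 11

    def test_round_trip_preserves_cells_and_missingness(self, table_copy, tmp_path):
        table = table_copy
        table.values.iloc[3, 5] = np.nan
        path = tmp_path / "cohort.tsv"
        dm.write_metabolite_table(table, path)
        back = dm.read_metabolite_table(path)
        pd.testing.assert_frame_equal(back.values, table.values)
        assert back.values.isna().sum().sum() == 1

    def test_empty_file_errors(self, tmp_path):
        df = _table_df(np.ones((1, 11))).iloc[:0]
        with pytest.raises(ValueError, match="no samples"):
            dm.read_metabolite_table(_write(tmp_path, df))

    def test_na_token_becomes_missing(self, tmp_path):
        df = _table_df(np.ones((4, 11))).astype(object)
        df.loc[1, "diOH-PVL"] = "NA"
        table = dm.read_metabolite_table(_write(tmp_path, df))
        assert table.values.isna().sum().sum() == 1
        assert table.values.shape == (4, 11)

    def test_unparseable_numeric_becomes_missing(self, tmp_path):
        df = _table_df(np.ones((4, 11))).astype(object)
        df.loc[2, "PPA-sulfate"] = "oops"
        table = dm.read_metabolite_table(_write(tmp_path, df))
        assert table.values.isna().sum().sum() == 1

    def test_duplicate_sample_id_is_hard_error(self, tmp_path):
        df = _table_df(np.ones((4, 11)))
        df.loc[2, "sample_id"] = "S0"
        with pytest.raises(dm.SchemaError, match="duplicate"):
            dm.read_metabolite_table(_write(tmp_path, df))

    def test_unknown_column_is_hard_error_naming_it(self, tmp_path):
        df = _table_df(np.ones((4, 11)))
        df["mystery-metabolite"] = 1.0
        with pytest.raises(dm.SchemaError, match="mystery-metabolite"):
            dm.read_metabolite_table(_write(tmp_path, df))


class TestAggregation:
    def test_term_counts_per_aglycone_group(self, table_copy):
        table = table_copy
        table.values.iloc[:, :] = 1.0
        agg = dm.aggregate_to_aglycones(table)
        row = agg.values.iloc[0]
        assert row["3'OH-PVL"] == 2
        assert row["4'OH-PVL"] == 1
        assert row["3'4'diOH-PVL"] == 6
        assert row["HPP"] == 2

    def test_schema_change_11_to_4(self, cohort):
        agg = dm.aggregate_to_aglycones(cohort.table)
        assert agg.n_variables == 4
        assert agg.aggregated
        assert not cohort.table.aggregated

    def test_all_zero_row_stays_zero(self, table_copy):
        table = table_copy
        table.values.iloc[0] = 0.0
        agg = dm.aggregate_to_aglycones(table)
        assert (agg.values.iloc[0] == 0).all()

    def test_mass_conservation(self, cohort):
        agg = dm.aggregate_to_aglycones(cohort.table)
        np.testing.assert_allclose(
            agg.values.sum(axis=1), cohort.table.values.sum(axis=1), rtol=1e-12
        )

    def test_missing_addend_propagates_unless_switched(self, table_copy):
        table = table_copy
        table.values.iloc[0, table.values.columns.get_loc("diOH-PVL")] = np.nan
        agg = dm.aggregate_to_aglycones(table)
        assert np.isnan(agg.values.iloc[0]["3'4'diOH-PVL"])
        agg0 = dm.aggregate_to_aglycones(table, missing_as_zero=True)
        assert not np.isnan(agg0.values.iloc[0]["3'4'diOH-PVL"])


def _ratio_table(sulf=2.0, gluc=4.0, n=4):
    values = pd.DataFrame(
        0.0,
        index=[f"S{i}" for i in range(n)],
        columns=dm.METABOLITE_NAMES_11,
    )
    values["PVL-3'-sulfate"] = sulf
    values["PVL-3'-glucuronide"] = gluc
    meta = pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "study": "acute",
            "condition": "716",
        },
        index=values.index,
    )
    return dm.MetaboliteTable(values, meta, dm.default_var_meta())


class TestRatios:
    def test_basic_arithmetic_and_dominance(self):
        rep = dm.sulfate_glucuronide_ratios(_ratio_table(2.0, 4.0))
        assert np.allclose(rep.ratios["overall"], 0.5)
        assert not rep.sulfate_dominant.any()

    def test_ratio_above_threshold_flags_sulfate_dominant(self):
        rep = dm.sulfate_glucuronide_ratios(_ratio_table(4.8, 4.0))  # ratio 1.2
        assert rep.sulfate_dominant.all()

    def test_diconjugate_and_free_aglycone_excluded(self):
        table = _ratio_table(2.0, 4.0)
        table.values["PVL-sulfate-glucuronide"] = 100.0
        table.values["diOH-PVL"] = 100.0
        rep = dm.sulfate_glucuronide_ratios(table)
        assert np.allclose(rep.ratios["overall"], 0.5)
        assert "PVL-sulfate-glucuronide" not in rep.sulfate_columns
        assert "PVL-sulfate-glucuronide" not in rep.glucuronide_columns

    def test_zero_glucuronide_sum_is_undefined_not_inf(self):
        rep = dm.sulfate_glucuronide_ratios(_ratio_table(2.0, 0.0))
        assert rep.ratios["overall"].isna().all()
        assert not rep.sulfate_dominant.any()
        assert rep.n_undefined > 0

    def test_scale_invariance(self, cohort):
        rep1 = dm.sulfate_glucuronide_ratios(cohort.table)
        scaled = dm.MetaboliteTable(
            cohort.table.values * 7.3,
            cohort.table.sample_meta,
            cohort.table.var_meta,
        )
        rep2 = dm.sulfate_glucuronide_ratios(scaled)
        pd.testing.assert_frame_equal(rep1.ratios, rep2.ratios)

    def test_diOH_dominated_cohort_correlates_with_overall(self, cohort):
        # diOH-group columns carry >= 90% of mass in the default cohort, so
        # the overall ratio must track the diOH ratio more than the HPP one
        rep = dm.sulfate_glucuronide_ratios(cohort.table)
        assert rep.correlations["3'4'diOH-PVL"] > rep.correlations["HPP"]
        # independent direct computation
        direct = rep.ratios["overall"].corr(rep.ratios["3'4'diOH-PVL"])
        assert np.isclose(direct, rep.correlations["3'4'diOH-PVL"])

    def test_methoxy_sulfate_class_switch(self):
        table = _ratio_table(2.0, 4.0)
        table.values["PVL-methoxy-sulfate"] = 2.0
        with_m = dm.sulfate_glucuronide_ratios(table, include_methoxy_sulfate=True)
        without = dm.sulfate_glucuronide_ratios(table, include_methoxy_sulfate=False)
        assert np.allclose(with_m.ratios["overall"], 1.0)
        assert np.allclose(without.ratios["overall"], 0.5)


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=0.1, max_value=1e4))
def test_ratio_scale_invariance_property(c):
    rep1 = dm.sulfate_glucuronide_ratios(_ratio_table(3.0, 5.0))
    rep2 = dm.sulfate_glucuronide_ratios(_ratio_table(3.0 * c, 5.0 * c))
    np.testing.assert_allclose(
        rep1.ratios["overall"], rep2.ratios["overall"], rtol=1e-9
    )
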