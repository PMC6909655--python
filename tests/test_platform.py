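"""Platform build: ingest, cleaning accounting, interpolation, derived columns."""

import numpy as np
import pandas as pd
import pytest

from gdperf import physiology, platform
from gdperf.synthetic import MEASUREMENT_COLUMNS


@pytest.fixture(scope="module")
def merged(small_raw_dir):
    return platform.ingest_and_merge(small_raw_dir)


@pytest.fixture(scope="module")
def cleaned(merged):
    return platform.clean(merged)


class TestIngest:
    def test_concatenates_all_patients(self, merged, small_cohort):
        assert len(merged) == small_cohort.n_rows
        assert set(merged["patient_id"]) == set(small_cohort.series)
        assert {"source_file", "source_row"} <= set(merged.columns)

    def test_saturations_converted_to_fractions(self, merged):
        sat = merged[["sao2", "svo2"]].dropna()
        assert ((sat > 0) & (sat <= 1)).all().all()

    def test_unparseable_timestamp_names_file_and_line(self, tmp_path):
        (tmp_path / "demographics.csv").write_text(
            "patient_id,age,sex,bsa,bmi\nP1,60,M,1.9,28\n")
        bad = tmp_path / "P1.csv"
        bad.write_text(
            "timestamp,patient_id,flow_lpm,hb_gdl,sao2_pct,svo2_pct,pao2_mmhg,map_mmhg\n"
            "2017-06-01 08:00:00,P1,4.2,10,98,75,250,70\n"
            "not-a-time,P1,4.2,10,98,75,250,70\n")
        with pytest.raises(ValueError, match=r"P1\.csv, line 3"):
            platform.ingest_and_merge(tmp_path)

    def test_unknown_patient_is_join_failure(self, tmp_path):
        (tmp_path / "demographics.csv").write_text(
            "patient_id,age,sex,bsa,bmi\nP1,60,M,1.9,28\n")
        (tmp_path / "P2.csv").write_text(
            "timestamp,patient_id,flow_lpm,hb_gdl,sao2_pct,svo2_pct,pao2_mmhg,map_mmhg\n"
            "2017-06-01 08:00:00,P2,4.2,10,98,75,250,70\n")
        with pytest.raises(ValueError, match="P2"):
            platform.ingest_and_merge(tmp_path)


class TestClean:
    def test_accounting_matches_corruption_ledger(self, merged, cleaned, small_cohort):
        df, report = cleaned
        led = small_cohort.ledger
        assert report.n_in == led.n_clean_rows + led.n_duplicates + led.n_empty
        assert report.n_duplicates == led.n_duplicates
        assert report.n_empty == led.n_empty
        assert report.n_out == led.n_clean_rows
        # conservation identity
        assert report.n_in == report.n_out + report.n_duplicates + report.n_empty

    def test_idempotent(self, cleaned):
        df, _ = cleaned
        again, report2 = platform.clean(df)
        assert report2.n_duplicates == 0 and report2.n_empty == 0
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), df.reset_index(drop=True))

    def test_key_uniqueness_after_cleaning(self, cleaned):
        df, _ = cleaned
        assert not df.duplicated(["patient_id", "timestamp"]).any()

    def test_empty_dataset(self):
        empty = pd.DataFrame(columns=["timestamp", "patient_id", *MEASUREMENT_COLUMNS])
        out, report = platform.clean(empty)
        assert len(out) == 0 and report.n_in == 0


class TestInterpolate:
    def _frame(self, hb_values, seconds=None):
        n = len(hb_values)
        seconds = seconds or [10 * i for i in range(n)]
        return pd.DataFrame({
            "timestamp": pd.Timestamp("2020-01-01") + pd.to_timedelta(seconds, unit="s"),
            "patient_id": "P1", "flow": 4.2, "hb": hb_values,
            "sao2": 0.98, "svo2": 0.75, "pao2": 250.0, "map": 70.0})

    def test_linear_midpoint(self):
        df = self._frame([9.0, np.nan, 10.0])
        out, rep = platform.interpolate_gaps(df, max_gap=120)
        assert out["hb"].iloc[1] == pytest.approx(9.5)
        assert out["interpolated_hb"].tolist() == [0, 1, 0]
        assert rep.n_cells_filled == 1

    def test_gap_longer_than_max_gap_left_missing(self):
        df = self._frame([9.0, np.nan, 10.0], seconds=[0, 100, 300])
        out, rep = platform.interpolate_gaps(df, max_gap=120)
        assert np.isnan(out["hb"].iloc[1])
        assert rep.n_cells_filled == 0 and rep.n_cells_left_missing == 1

    def test_leading_and_trailing_gaps_left_missing(self):
        df = self._frame([np.nan, 9.5, np.nan])
        out, _ = platform.interpolate_gaps(df, max_gap=1e6)
        assert np.isnan(out["hb"].iloc[0]) and np.isnan(out["hb"].iloc[2])

    def test_never_interpolates_across_patients(self):
        a = self._frame([9.0, np.nan])
        b = self._frame([np.nan, 12.0])
        b["patient_id"] = "P2"
        df = pd.concat([a, b], ignore_index=True)
        out, rep = platform.interpolate_gaps(df, max_gap=1e6)
        assert rep.n_cells_filled == 0

    def test_idempotent_on_real_data(self, cleaned):
        df, _ = cleaned
        once, _ = platform.interpolate_gaps(df, max_gap=120)
        twice, rep2 = platform.interpolate_gaps(once, max_gap=120)
        assert rep2.n_cells_filled == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_no_missing_cells_is_noop(self):
        df = self._frame([9.0, 9.5, 10.0])
        out, rep = platform.interpolate_gaps(df)
        assert rep.n_cells_filled == 0
        pd.testing.assert_frame_equal(out[df.columns], df)


class TestDerive:
    def test_example_row(self):
        df = pd.DataFrame({
            "timestamp": [pd.Timestamp("2020-01-01")], "patient_id": ["P1"],
            "flow": [4.29], "hb": [10.0], "sao2": [1.0], "svo2": [0.68],
            "pao2": [0.0], "map": [70.0]})
        demo = pd.DataFrame({"patient_id": ["P1"], "bsa": [1.95]})
        out = platform.derive_columns(df, demo)
        assert out["ci"].iloc[0] == pytest.approx(2.2)
        assert out["do2i"].iloc[0] == pytest.approx(299.2)
        assert out["o2er"].iloc[0] == pytest.approx(0.32)

    def test_recomputation_oracle(self, clean_platform):
        df = clean_platform
        expect = physiology.do2i(
            df["flow"].to_numpy(), df["bsa"].to_numpy(), df["hb"].to_numpy(),
            df["sao2"].to_numpy(), df["pao2"].to_numpy(), validate=False)
        assert np.nanmax(np.abs(df["do2i"].to_numpy() - expect)) < 1e-9

    def test_incomplete_rows_have_missing_derived_cells(self):
        df = pd.DataFrame({
            "timestamp": [pd.Timestamp("2020-01-01 00:00:00"),
                          pd.Timestamp("2020-01-01 00:00:10")],
            "patient_id": "P1", "flow": [4.2, 4.2], "hb": [10.0, 10.0],
            "sao2": [0.98, 0.98], "svo2": [np.nan, 0.7],
            "pao2": [250.0, 250.0], "map": [70.0, 70.0]})
        demo = pd.DataFrame({"patient_id": ["P1"], "bsa": [1.95]})
        out = platform.derive_columns(df, demo)
        assert out["complete"].tolist() == [0, 1]
        assert np.isnan(out["do2i"].iloc[0]) and not np.isnan(out["do2i"].iloc[1])

    def test_patient_without_bsa_rejected(self):
        df = pd.DataFrame({
            "timestamp": [pd.Timestamp("2020-01-01")], "patient_id": ["P9"],
            "flow": [4.2], "hb": [10.0], "sao2": [0.98], "svo2": [0.7],
            "pao2": [250.0], "map": [70.0]})
        demo = pd.DataFrame({"patient_id": ["P1"], "bsa": [1.95]})
        with pytest.raises(ValueError, match="P9"):
            platform.derive_columns(df, demo)
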