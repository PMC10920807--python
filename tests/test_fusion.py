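"""Half-hour averaging, gap-aware upsampling, quality filtering, assembly."""

import warnings

import numpy as np
import pandas as pd
import pytest

from abitower.dqf import encode_bitmask, load_schema
from abitower.fixtures import FixtureConfig, generate_scene_stack
from abitower.fusion import (
    CadenceError,
    QualityPolicy,
    WindowError,
    apply_quality_filters,
    assemble_site_timeseries,
    halfhour_average,
    no_filtering_policy,
    upsample_hourly,
)
from abitower.geometry import GeodeticLocation
from abitower.products import SiteInfo, TABLE2_COLUMNS


class TestHalfHourAverage:
    def test_three_scans_mean_stamped_at_window_end(self):
        scans = [
            ("2022-06-01 15:00", 100.0, 8),
            ("2022-06-01 15:10", 110.0, 8),
            ("2022-06-01 15:20", 120.0, 8),
        ]
        out = halfhour_average(scans)
        assert out["value"] == pytest.approx(110.0)
        assert out["utc_time"] == pd.Timestamp("2022-06-01 15:30")
        assert out["n_scans"] == 3

    def test_thirty_minute_scan_opens_next_window(self):
        with pytest.raises(WindowError):
            halfhour_average(
                [("2022-06-01 15:20", 1.0, 8), ("2022-06-01 15:30", 2.0, 8)]
            )

    def test_invalid_middle_scan_excluded(self):
        scans = [
            ("2022-06-01 15:00", 100.0, 8),
            ("2022-06-01 15:10", 999.0, 24),
            ("2022-06-01 15:20", 120.0, 8),
        ]
        out = halfhour_average(scans, is_valid=lambda v, q: q == 8)
        assert out["value"] == pytest.approx(110.0)
        assert out["n_scans"] == 2
        assert out["dqf"] == 8

    def test_worst_flag_kept(self):
        out = halfhour_average(
            [("2022-06-01 15:00", 1.0, 8), ("2022-06-01 15:10", 2.0, 16)]
        )
        assert out["dqf"] == 16

    def test_all_invalid_window_is_missing_with_flag(self):
        out = halfhour_average(
            [("2022-06-01 15:00", np.nan, 26), ("2022-06-01 15:10", np.nan, 24)]
        )
        assert np.isnan(out["value"])
        assert out["dqf"] == 26
        assert out["n_scans"] == 0

    def test_empty_window(self):
        assert halfhour_average([]) is None


class TestUpsampleHourly:
    def test_anchors_preserved_exactly(self):
        idx = pd.date_range("2022-06-01", periods=6, freq="h")
        series = pd.Series([0.0, 3.0, 1.0, 4.0, 1.5, 9.0], index=idx)
        values, flags = upsample_hourly(series)
        for t, v in series.items():
            assert values[t] == v
            assert not flags[t]

    def test_linear_input_interpolates_to_midpoints(self):
        idx = pd.date_range("2022-06-01", periods=5, freq="h")
        series = pd.Series(np.arange(5.0) * 10.0, index=idx)
        values, flags = upsample_hourly(series)
        for k in range(4):
            t = idx[k] + pd.Timedelta(minutes=30)
            assert values[t] == pytest.approx((series.iloc[k] + series.iloc[k + 1]) / 2)
            assert flags[t]

    def test_gap_rule_no_fill_across_missing_hour(self):
        idx = pd.to_datetime(
            ["2022-06-01 10:00", "2022-06-01 12:00"]  # 11:00 missing
        )
        values, _ = upsample_hourly(pd.Series([5.0, 9.0], index=idx))
        assert pd.Timestamp("2022-06-01 10:30") not in values.index
        assert pd.Timestamp("2022-06-01 11:00") not in values.index
        assert pd.Timestamp("2022-06-01 11:30") not in values.index

    def test_insertion_count_equals_adjacent_pairs(self):
        idx = pd.date_range("2022-06-01", periods=10, freq="h")
        series = pd.Series(np.arange(10.0), index=idx)
        series.iloc[[3, 7]] = np.nan  # two gaps
        values, flags = upsample_hourly(series)
        present = series.dropna()
        pairs = sum(
            1
            for a, b in zip(present.index, present.index[1:])
            if b - a == pd.Timedelta(hours=1)
        )
        assert int(flags.sum()) == pairs

    def test_monotone_input_no_overshoot(self):
        idx = pd.date_range("2022-06-01", periods=8, freq="h")
        series = pd.Series([0.0, 1.0, 8.0, 9.0, 9.5, 20.0, 21.0, 40.0], index=idx)
        values, flags = upsample_hourly(series)
        inserted = values[flags]
        for t, v in inserted.items():
            lo = series[t - pd.Timedelta(minutes=30)]
            hi = series[t + pd.Timedelta(minutes=30)]
            assert min(lo, hi) <= v <= max(lo, hi)

    def test_non_hourly_input_rejected(self):
        idx = pd.to_datetime(["2022-06-01 10:00", "2022-06-01 10:30"])
        with pytest.raises(CadenceError):
            upsample_hourly(pd.Series([1.0, 2.0], index=idx))


class TestQualityFilters:
    def _record(self, brf_dqf=8, dsr_dqf=0, adp_dqf=0):
        return pd.DataFrame(
            {
                "BRF2": [0.1],
                "BRF3": [0.4],
                "BRF_DQF": [brf_dqf],
                "DSR": [500.0],
                "DSR_DQF": [dsr_dqf],
                "CMI_C02": [0.15],
                "ADP_DQF": [adp_dqf],
                "NDVI": [0.6],
                "NIRv": [0.24],
                "NIRvP": [54.0],
            }
        )

    def test_all_clear_record_unchanged(self):
        rec = self._record()
        out = apply_quality_filters(rec)
        pd.testing.assert_frame_equal(out, rec)

    def test_cloudy_brf_blanked_cmi_untouched(self):
        out = apply_quality_filters(self._record(brf_dqf=16))
        assert np.isnan(out["BRF2"].iloc[0])
        assert np.isnan(out["BRF3"].iloc[0])
        assert out["CMI_C02"].iloc[0] == 0.15
        assert out["BRF_DQF"].iloc[0] == 16  # raw flag retained

    def test_invalid_dsr_blanked(self):
        out = apply_quality_filters(self._record(dsr_dqf=1))
        assert np.isnan(out["DSR"].iloc[0])

    def test_snow_masks_index_family_not_par(self):
        schema = load_schema("adp")
        snow = encode_bitmask({"snow_ice_cloud": 1}, schema)
        rec = self._record(adp_dqf=snow)
        rec["PAR"] = 225.0
        out = apply_quality_filters(rec)
        assert np.isnan(out["NDVI"].iloc[0])
        assert np.isnan(out["NIRv"].iloc[0])
        assert np.isnan(out["NIRvP"].iloc[0])
        assert out["PAR"].iloc[0] == 225.0

    def test_disabled_policy_is_identity(self):
        rec = self._record(brf_dqf=16, dsr_dqf=1)
        out = apply_quality_filters(rec, no_filtering_policy())
        pd.testing.assert_frame_equal(out, rec)

    def test_policy_yaml_round_trip(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("brf_keep_dqf: [8, 16]\nsnow_mask_indices: false\n")
        policy = QualityPolicy.from_yaml(path)
        assert policy.brf_keep_dqf == (8, 16)
        assert policy.snow_mask_indices is False

    def test_unknown_policy_key_rejected(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("keep_everything: true\n")
        with pytest.raises(KeyError):
            QualityPolicy.from_yaml(path)


class TestAssembly:
    def test_row_counts(self, noiseless_assembled):
        cfg, _, assembled = noiseless_assembled
        for df in assembled.values():
            # one row per half hour across the span
            assert len(df) == cfg.days * 48
            assert list(df.columns) == TABLE2_COLUMNS

    def test_week_of_synthetic_data_has_336_rows(self):
        cfg = FixtureConfig(seed=23, days=7, products=("ACM",)).noiseless()
        result = generate_scene_stack(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = assemble_site_timeseries(cfg.sites[0], result.scenes)
        assert len(df) == 336

    def test_interval_end_stamping(self, noiseless_assembled):
        _, _, assembled = noiseless_assembled
        df = next(iter(assembled.values()))
        assert set(df["UTC_TIME"].dt.minute.unique()) <= {0, 30}
        assert df.index[0].minute == 30

    def test_local_time_fixed_offset(self, noiseless_assembled):
        cfg, _, assembled = noiseless_assembled
        for site in cfg.sites:
            df = assembled[site.site_id]
            delta = (df["LOCAL_TIME"] - df["UTC_TIME"]).unique()
            assert len(delta) == 1
            assert delta[0] == pd.Timedelta(hours=site.utc_offset_hours)

    def test_solar_fields_consistent(self, noiseless_assembled):
        _, _, assembled = noiseless_assembled
        df = next(iter(assembled.values()))
        np.testing.assert_allclose(
            df["SOLAR_POS"].astype(float),
            df["SZA"].astype(float) + df["SAA"].astype(float),
        )

    def test_high_vza_site_warns_and_blanks_reflectance(self):
        cfg = FixtureConfig(
            seed=31,
            days=1,
            products=("BRF",),
            sites=(
                SiteInfo("SYN-SEA", GeodeticLocation(47.61, -122.33, 0.0), -8.0),
            ),
        ).noiseless()
        result = generate_scene_stack(cfg)
        with pytest.warns(UserWarning, match="VZA"):
            df = assemble_site_timeseries(cfg.sites[0], result.scenes)
        assert df["BRF2"].isna().all()

    def test_filtering_commutes_with_averaging_on_clear_data(self):
        cfg = FixtureConfig(seed=41, days=1, cloud_probability=0.0,
                            products=("BRF",)).noiseless()
        result = generate_scene_stack(cfg)
        site = cfg.sites[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered = assemble_site_timeseries(site, result.scenes)
            raw = assemble_site_timeseries(
                site, result.scenes, policy=no_filtering_policy()
            )
        a = filtered["BRF2"].astype(float)
        b = raw["BRF2"].astype(float)
        assert ((a == b) | (a.isna() & b.isna())).all()
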