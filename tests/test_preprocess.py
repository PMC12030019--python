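"""Preprocessing: Gaussian denoising, Tukey-fence screening, linear
imputation, feature assembly and min-max scaling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cropcast as cc
from cropcast.preprocess import (GaussianFilterSpec, MinMaxScaler1D,
                                 SensorFrame, build_features, clean_channel,
                                 gaussian_smooth, interpolate_missing,
                                 quartile_summary, screen_outliers,
                                 screen_outliers_windowed)


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

class TestGaussianSmooth:
    def test_constant_preserved(self):
        out = gaussian_smooth(np.full(50, 3.7), GaussianFilterSpec(sigma=4))
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_impulse_reproduces_normalised_kernel(self):
        # independent oracle: evaluate the Gaussian density at integer
        # offsets and normalise to unit sum
        sigma, radius = 2.0, 8
        x = np.arange(-radius, radius + 1)
        kern = np.exp(-x**2 / (2 * sigma**2))
        kern /= kern.sum()
        impulse = np.zeros(2 * radius + 1)
        impulse[radius] = 1.0
        out = gaussian_smooth(impulse, GaussianFilterSpec(sigma=sigma, radius=radius))
        np.testing.assert_allclose(out, kern, atol=1e-12)

    def test_default_sigma_10_kernel_unit_sum(self):
        spec = GaussianFilterSpec()
        assert spec.sigma == 10.0
        assert spec.radius == 40
        k = spec.kernel()
        assert abs(k.sum() - 1.0) < 1e-12
        # matches the continuous density up to normalisation
        x = np.arange(-40, 41)
        expected = np.exp(-x**2 / 200.0)
        np.testing.assert_allclose(k, expected / expected.sum(), atol=1e-12)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            GaussianFilterSpec(sigma=0.0)
        with pytest.raises(ValueError):
            GaussianFilterSpec(sigma=-3.0)

    def test_shift_equivariance_interior(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        spec = GaussianFilterSpec(sigma=3, radius=12)
        a = gaussian_smooth(y, spec)
        b = gaussian_smooth(np.roll(y, 7), spec)
        # away from the boundary a shifted input gives a shifted output
        np.testing.assert_allclose(a[50:200], np.roll(b, -7)[50:200], atol=1e-9)

    def test_periodic_mean_preserved(self):
        t = np.arange(240)
        y = 5.0 + 2.0 * np.sin(2 * np.pi * t / 24)
        out = gaussian_smooth(y, GaussianFilterSpec(sigma=6))
        assert abs(out.mean() - y.mean()) < 1e-2


# ---------------------------------------------------------------------------
# quartiles and the 1.5 IQR fence
# ---------------------------------------------------------------------------

def _quantile_oracle(values, p):
    """Independent sort-and-interpolate quantile (fractional rank p*(n-1))."""
    v = np.sort(np.asarray(values, dtype=float))
    h = p * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestQuartiles:
    def test_all_equal_degenerate(self):
        s = quartile_summary(np.full(10, 4.2))
        assert s.iqr == 0
        assert s.lower_bound == s.upper_bound == 4.2

    def test_matches_brute_force_oracle(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        s = quartile_summary(vals)
        q1 = _quantile_oracle(vals, 0.25)
        q3 = _quantile_oracle(vals, 0.75)
        assert s.q1 == pytest.approx(q1)
        assert s.q3 == pytest.approx(q3)
        assert s.lower_bound == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert s.upper_bound == pytest.approx(q3 + 1.5 * (q3 - q1))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_oracle_agreement_property(self, values):
        s = quartile_summary(np.array(values))
        assert s.q1 == pytest.approx(_quantile_oracle(values, 0.25), abs=1e-9)
        assert s.q2 == pytest.approx(_quantile_oracle(values, 0.50), abs=1e-9)
        assert s.q3 == pytest.approx(_quantile_oracle(values, 0.75), abs=1e-9)
        assert s.q1 <= s.q2 <= s.q3

    def test_spike_beyond_collapsed_bounds(self):
        vals = np.array([0.0] * 31 + [100.0])
        s = quartile_summary(vals)
        assert s.upper_bound == 0.0
        assert vals.max() > s.upper_bound

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            quartile_summary(np.array([1.0, 2.0, 3.0]))


class TestScreenOutliers:
    def test_clean_series_is_identity(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        flags, cleaned = screen_outliers(vals)
        assert not flags.any()
        np.testing.assert_array_equal(cleaned, vals)

    def test_spike_replaced_by_nonflagged_mean(self):
        vals = np.array([0.0] * 31 + [100.0])
        flags, cleaned = screen_outliers(vals)
        assert flags.sum() == 1 and flags[-1]
        assert cleaned[-1] == 0.0

    def test_injected_spikes_all_flagged(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 1, 400)
        s = quartile_summary(vals)
        idx = rng.choice(400, size=7, replace=False)
        vals[idx] = s.upper_bound + rng.uniform(5, 10, size=7)
        flags, cleaned = screen_outliers(vals)
        assert set(np.flatnonzero(flags)) >= set(idx)
        keep = ~flags
        assert cleaned[flags][0] == pytest.approx(vals[keep].mean())

    def test_shift_invariance_of_flags(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=200)
        vals[10] = 50.0
        f1, _ = screen_outliers(vals)
        f2, _ = screen_outliers(vals + 123.4)
        np.testing.assert_array_equal(f1, f2)

    def test_all_flagged_raises(self):
        vals = np.array([0.0] * 31 + [100.0])
        s = quartile_summary(vals)
        with pytest.raises(ValueError):
            screen_outliers(np.full(8, 50.0), s)

    def test_windowed_screen_covers_full_series(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=500)
        vals[[100, 400]] = 60.0
        flags, cleaned = screen_outliers_windowed(vals, window_h=216)
        assert flags[100] and flags[400]
        assert np.abs(cleaned).max() < 10


# ---------------------------------------------------------------------------
# linear imputation
# ---------------------------------------------------------------------------

class TestInterpolateMissing:
    def test_linear_signal_recovered_exactly(self):
        t = np.arange(50, dtype=float)
        y = 2 * t + 1
        gappy = y.copy()
        gappy[[3, 4, 5, 20, 33]] = np.nan
        np.testing.assert_allclose(interpolate_missing(gappy, t), y, atol=1e-12)

    def test_midpoint(self):
        out = interpolate_missing(np.array([4.0, np.nan, 10.0]),
                                  np.array([0.0, 1.0, 2.0]))
        assert out[1] == pytest.approx(7.0)

    def test_multihour_gap_follows_chord(self):
        t = np.arange(10, dtype=float)
        y = np.array([0, 1, 2, np.nan, np.nan, np.nan, 12, 13, 14, 15], float)
        out = interpolate_missing(y, t)
        # chord between (2, 2) and (6, 12): slope 2.5
        np.testing.assert_allclose(out[3:6], [4.5, 7.0, 9.5])

    def test_boundary_gap_nearest_extension(self):
        y = np.array([np.nan, np.nan, 5.0, 6.0, np.nan], float)
        out = interpolate_missing(y)
        np.testing.assert_allclose(out, [5, 5, 5, 6, 6])

    def test_insufficient_observations(self):
        with pytest.raises(ValueError):
            interpolate_missing(np.array([np.nan, 3.0, np.nan]))

    @given(st.sets(st.integers(1, 38), min_size=1, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_fixed_point_property(self, gaps):
        t = np.arange(40, dtype=float)
        y = -0.7 * t + 3.0
        gappy = y.copy()
        gappy[list(gaps)] = np.nan
        np.testing.assert_allclose(interpolate_missing(gappy, t), y, atol=1e-9)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def _frame_from(cols: dict, hours: int = 48) -> SensorFrame:
    idx = pd.date_range("2024-04-01", periods=hours, freq="h")
    return SensorFrame(pd.DataFrame(cols, index=idx), "A1")


class TestBuildFeatures:
    def _two_node_frame(self, m1, m2, hours=48):
        base = {
            "soil_temp_C_n1": np.full(hours, 17.0),
            "soil_moist_pct_n1": m1,
            "soil_cond_uScm_n1": np.full(hours, 600.0),
            "soil_temp_C_n2": np.full(hours, 17.0),
            "soil_moist_pct_n2": m2,
            "soil_cond_uScm_n2": np.full(hours, 600.0),
            "air_temp_C": np.linspace(10, 24, hours),
            "air_hum_pct": np.linspace(60, 80, hours),
        }
        return _frame_from(base, hours)

    def test_identical_nodes_zero_differences(self):
        m = np.linspace(40, 25, 48)
        fm = build_features(self._two_node_frame(m, m),
                            status=np.linspace(0.2, 0.8, 48), clean=False)
        diff = fm.scaler.inverse_transform(fm.features)["soil_moist_pct_diff"]
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_difference_and_adjacent_mean_arithmetic(self):
        m1 = np.full(48, 30.0)
        m2 = np.full(48, 20.0)
        m1[5], m2[5] = 30.0, 20.0
        fm = build_features(self._two_node_frame(m1, m2),
                            status=np.linspace(0.2, 0.8, 48), clean=False)
        raw = fm.scaler.inverse_transform(fm.features)
        assert raw["soil_moist_pct_diff"].iloc[5] == pytest.approx(10.0)
        assert raw["soil_moist_pct_mean"].iloc[5] == pytest.approx(25.0)

    def test_scaler_roundtrip_and_unit_interval(self, small_season):
        fm = build_features(small_season.frame, status=small_season.status)
        assert (fm.features.to_numpy() >= -1e-12).all()
        assert (fm.features.to_numpy() <= 1 + 1e-12).all()
        back = fm.scaler.inverse_transform(fm.scaler.transform(
            fm.scaler.inverse_transform(fm.features)))
        np.testing.assert_allclose(
            back.to_numpy(), fm.scaler.inverse_transform(fm.features).to_numpy(),
            atol=1e-9)

    def test_requires_exactly_one_target_source(self, small_season):
        with pytest.raises(ValueError):
            build_features(small_season.frame)

    def test_scaler_json_roundtrip(self, small_season):
        fm = build_features(small_season.frame, status=small_season.status)
        sc = MinMaxScaler1D.from_json(fm.scaler.to_json())
        assert sc.data_min == fm.scaler.data_min
        assert sc.data_max == fm.scaler.data_max

    def test_status_from_weekly_heights(self):
        frame = self._two_node_frame(np.full(200, 30.0), np.full(200, 28.0), 200)
        heights = {"dates": ["2024-04-01", "2024-04-08"],
                   "mean_height_mm": [190.0, 200.0]}
        fm = build_features(frame, heights=heights, clean=False)
        assert fm.target.iloc[0] == pytest.approx(0.0)
        assert fm.target.is_monotonic_increasing

    def test_clean_chain_imputes_and_flags(self, small_season):
        corrupted, truth = cc.inject_artifacts(
            small_season.frame,
            cc.SimulatorConfig(anomaly=cc.synthetic.AnomalyConfig(
                spike_prob=0.002, missing_prob=0.005)), seed=4)
        fm = build_features(corrupted, status=small_season.status)
        assert fm.qc["imputed"] == sum(m.sum() for m in truth["missing"].values())
        assert not fm.features.isna().any().any()


class TestSensorFrameInvariants:
    def test_rejects_irregular_grid(self):
        idx = pd.DatetimeIndex(["2024-04-01 00:00", "2024-04-01 01:00",
                                "2024-04-01 03:00"])
        with pytest.raises(ValueError):
            SensorFrame(pd.DataFrame({"a": [1, 2, 3]}, index=idx))

    def test_rejects_unsorted(self):
        idx = pd.DatetimeIndex(["2024-04-01 01:00", "2024-04-01 00:00"])
        with pytest.raises(ValueError):
            SensorFrame(pd.DataFrame({"a": [1, 2]}, index=idx))
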