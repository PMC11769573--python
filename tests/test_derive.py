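"""Derivation chain: decimation, AMP, moving correlation, CPP, validity
filtering, and multi-resolution resampling."""

import numpy as np
import pytest
from scipy import stats

from rapkit import derive, synth
from rapkit.core import IndexSeries, InvalidParameterError, PhysioRecording
from .conftest import make_series


def _recording(values, fs=100.0, channel="ICP"):
    values = np.asarray(values, dtype=float)
    return PhysioRecording(
        time=np.arange(values.size) / fs, channels={channel: values}, sample_rate=fs
    )


class TestDecimate:
    def test_constant_signal(self):
        s = derive.decimate_10s(_recording(np.full(3000, 12.0)), "ICP")
        assert np.allclose(s.values, 12.0)
        assert len(s) == 3

    def test_ramp_matches_brute_force_block_means(self):
        values = np.arange(2000) / 100.0  # 20-s ramp at 100 Hz
        s = derive.decimate_10s(_recording(values), "ICP")
        expected = [values[:1000].mean(), values[1000:].mean()]
        assert np.allclose(s.values, expected)

    def test_partial_trailing_block_dropped(self):
        s = derive.decimate_10s(_recording(np.ones(2500)), "ICP")  # 25 s
        assert len(s) == 2

    def test_too_short_raises(self):
        with pytest.raises(InvalidParameterError):
            derive.decimate_10s(_recording(np.ones(500)), "ICP")  # 5 s


class TestComputeAmp:
    def test_pure_sinusoid_amplitude_recovered(self):
        t = np.arange(3000) / 100.0
        rec = _recording(20.0 + 2.0 * np.sin(2 * np.pi * 1.2 * t))
        amp = derive.compute_amp(rec)
        assert np.allclose(amp.values, 2.0, rtol=0.02)

    def test_off_bin_frequency_within_tolerance(self):
        # 1.15 Hz sits between 0.1-Hz bins: worst-case scalloping regime
        t = np.arange(3000) / 100.0
        rec = _recording(20.0 + 3.0 * np.sin(2 * np.pi * 1.15 * t))
        amp = derive.compute_amp(rec)
        assert np.allclose(amp.values, 3.0, rtol=0.05)

    def test_flatline_yields_zero_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            amp = derive.compute_amp(_recording(np.full(2000, 15.0)))
        assert np.allclose(amp.values, 0.0)

    def test_generator_ground_truth(self, short_recording):
        amp = derive.compute_amp(short_recording)
        # generator modulates around pulse_amplitude=2 with lognormal factor
        assert 1.0 < np.nanmean(amp.values) < 4.0


class TestMovingCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        x = make_series(np.random.default_rng(0).normal(size=60), "10s")
        y = make_series(2.0 * x.values + 3.0, "10s")
        r = derive.moving_correlation(x, y)
        assert np.allclose(r.dropna(), 1.0)

    def test_negated_parent_flips_sign(self):
        x = make_series(np.random.default_rng(1).normal(size=60), "10s")
        y = make_series(-x.values, "10s")
        r = derive.moving_correlation(x, y)
        assert np.allclose(r.dropna(), -1.0)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x = make_series(rng.normal(size=300), "10s")
        y = make_series(rng.normal(size=300), "10s")
        r = derive.moving_correlation(x, y)
        for i, end in enumerate(range(29, 300, 6)):
            expected = stats.pearsonr(
                x.values[end - 29 : end + 1], y.values[end - 29 : end + 1]
            ).statistic
            assert r.values[i] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_window_is_missing(self):
        x = make_series(np.ones(40), "10s")
        y = make_series(np.random.default_rng(3).normal(size=40), "10s")
        r = derive.moving_correlation(x, y)
        assert np.isnan(r.values).all()

    def test_emission_grid_and_alignment(self):
        x = make_series(np.random.default_rng(4).normal(size=90), "10s")
        y = make_series(np.random.default_rng(5).normal(size=90), "10s")
        r = derive.moving_correlation(x, y)
        # first emission at the end of the first full 5-min window
        assert r.time[0] == x.time[29]
        assert r.resolution == "1min"
        assert np.allclose(np.diff(r.time), 60.0)


class TestCppAndValidity:
    def test_cpp_is_map_minus_icp(self):
        icp = make_series([15.0, 20.0, np.nan])
        map_ = make_series([80.0, 90.0, 85.0])
        cpp = derive.compute_cpp(map_, icp)
        assert cpp.values[0] == 65.0
        assert np.isnan(cpp.values[2])
        # identity: CPP + ICP == MAP wherever defined
        assert np.allclose((cpp.values + icp.values)[:2], map_.values[:2])

    def test_validity_filter_blanks_dependents(self):
        icp = make_series([15.0, 150.0, 20.0], name="ICP")
        map_ = make_series([90.0, 95.0, 100.0], name="MAP")
        rap = make_series([0.5, 0.6, 0.7], name="RAP")
        out = derive.apply_validity_filter({"ICP": icp, "MAP": map_, "RAP": rap})
        assert np.isnan(out["ICP"].values[1])
        assert np.isnan(out["MAP"].values[1])
        assert np.isnan(out["RAP"].values[1])
        assert out["RAP"].values[0] == 0.5

    def test_validity_filter_identity_when_in_bounds(self):
        icp = make_series([15.0, 20.0], name="ICP")
        map_ = make_series([90.0, 95.0], name="MAP")
        out = derive.apply_validity_filter({"ICP": icp, "MAP": map_})
        assert np.array_equal(out["ICP"].values, icp.values)

    def test_removed_count_matches_brute_force(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 60, 500)  # many out-of-bounds values
        icp = make_series(vals, name="ICP")
        map_ = make_series(rng.normal(90, 10, 500), name="MAP")
        out = derive.apply_validity_filter({"ICP": icp, "MAP": map_})
        expected_bad = np.sum((vals > 100) | (vals < -15))
        assert np.isnan(out["ICP"].values).sum() == expected_bad


class TestResample:
    def test_constant_series(self):
        s = make_series(np.full(120, 7.0))
        for res in ("10min", "30min", "60min"):
            out = derive.resample_mean(s, res)
            assert np.allclose(out.values, 7.0)

    def test_hourly_mean_of_1_to_60(self):
        s = make_series(np.arange(1.0, 61.0))
        out = derive.resample_mean(s, "60min")
        assert out.values == pytest.approx([30.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=235)
        s = make_series(vals)
        out = derive.resample_mean(s, "10min")
        expected = [vals[i * 10 : (i + 1) * 10].mean() for i in range(23)]
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_majority_missing_block_is_missing(self):
        vals = np.arange(20.0)
        vals[:6] = np.nan
        out = derive.resample_mean(make_series(vals), "10min")
        assert np.isnan(out.values[0]) and not np.isnan(out.values[1])

    def test_unsupported_resolution(self):
        with pytest.raises(InvalidParameterError):
            derive.resample_mean(make_series(np.ones(60)), "5min")


class TestFullChain:
    def test_deterministic(self, short_recording):
        a = derive.derive_indices(short_recording)
        b = derive.derive_indices(short_recording)
        for k in a:
            assert np.array_equal(a[k].values, b[k].values, equal_nan=True)

    def test_rap_prx_bounded(self, coupled_recording):
        idx = derive.derive_indices(coupled_recording)
        for name in ("RAP", "PRx"):
            v = idx[name].dropna()
            assert np.all(v >= -1.0) and np.all(v <= 1.0)

    def test_high_coupling_gives_high_rap(self, coupled_recording):
        idx = derive.derive_indices(coupled_recording)
        assert np.nanmean(idx["RAP"].values) > 0.5
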