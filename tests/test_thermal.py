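"""Thermal analytics: daily means, diurnal profiles, cooling, attenuation."""

import numpy as np
import pandas as pd
import pytest

from phenoroof.synthetic import SensorSimSpec, generate_sensor_suite
from phenoroof.thermal import (
    NoOverlapError,
    SensorSeries,
    climate_table,
    cooling_effect,
    daily_means,
    diurnal_cooling,
    diurnal_profile,
    substrate_attenuation,
)

WINDOW = dict(start="2022-08-01", end="2022-08-11")


def _series(values, index, role="crop-15cm", station="s", crop=None,
            variable="temperature"):
    return SensorSeries(station=station, role=role, crop=crop, variable=variable,
                        values=pd.Series(values, index=index))


def _sim(name="s", **kw):
    defaults = dict(WINDOW)
    defaults.update(kw)
    (out,) = generate_sensor_suite({name: SensorSimSpec(**defaults)})
    return out


class TestDailyMeans:
    def test_constant_series(self):
        idx = pd.date_range("2022-08-01", "2022-08-04", freq="15min",
                            inclusive="left")
        dm = daily_means(_series(np.full(len(idx), 20.0), idx))
        assert len(dm.means) == 3
        assert np.allclose(dm.means, 20.0)

    def test_noiseless_sinusoid_daily_mean_equals_mean_parameter(self):
        s = _sim(diurnal_mean_C=21.5, diurnal_amplitude_C=7.0, cooling_offset_C=1.0)
        dm = daily_means(s)
        assert np.allclose(dm.means, 20.5, atol=1e-12)

    def test_gappy_series_matches_groupby_oracle(self, rng):
        s = _sim(noise_sd_C=0.5, missing_fraction=0.1, seed=77)
        dm = daily_means(s, completeness_min=0.5)
        v = s.values
        for day in dm.means.index:
            sel = v[(v.index >= day) & (v.index < day + pd.Timedelta(days=1))]
            assert dm.means[day] == pytest.approx(sel.to_numpy().mean(), rel=1e-12)

    def test_incomplete_days_excluded_and_reported(self):
        idx = pd.date_range("2022-08-01", "2022-08-03", freq="15min",
                            inclusive="left")
        keep = ~((idx >= "2022-08-02") & (idx < "2022-08-02 12:00"))
        dm = daily_means(_series(np.full(keep.sum(), 5.0), idx[keep]))
        assert list(dm.means.index) == [pd.Timestamp("2022-08-01")]
        assert pd.Timestamp("2022-08-02") in dm.excluded_days


class TestDiurnalProfile:
    def test_sinusoid_peak_hour_recovered(self):
        for cadence in (10, 15):
            s = _sim(cadence_minutes=cadence, peak_hour=15.0)
            prof = diurnal_profile(s, "2022-08")
            assert prof.peak_hour == 15

    def test_constant_series_flat_profile(self):
        idx = pd.date_range("2022-08-01", "2022-08-05", freq="15min",
                            inclusive="left")
        prof = diurnal_profile(_series(np.full(len(idx), 9.0), idx), "2022-08")
        assert np.allclose(prof.hourly_mean, 9.0)
        assert prof.hourly_n.sum() == len(idx)

    def test_mixed_cadences_each_match_groupby_oracle(self):
        for cadence in (10, 15):
            s = _sim(cadence_minutes=cadence, noise_sd_C=0.4, seed=5)
            prof = diurnal_profile(s, "2022-08")
            for h in range(24):
                sel = s.values[s.values.index.hour == h]
                assert prof.hourly_mean[h] == pytest.approx(sel.mean(), rel=1e-12)
                assert prof.hourly_n[h] == len(sel)

    def test_no_overlap_rejected(self):
        with pytest.raises(NoOverlapError):
            diurnal_profile(_sim(), "2023-01")

    def test_amplitude_recovered_within_cadence_step(self):
        s = _sim(diurnal_amplitude_C=8.0, cadence_minutes=15)
        prof = diurnal_profile(s, "2022-08")
        half_range = (np.nanmax(prof.hourly_mean) - np.nanmin(prof.hourly_mean)) / 2
        assert half_range == pytest.approx(8.0, abs=0.2)


class TestCoolingEffect:
    def test_identical_series_zero(self):
        s = _sim()
        cs = cooling_effect(s, s)
        assert np.allclose(cs.daily_deltas, 0.0)
        assert cs.mean == 0.0 and cs.max == 0.0

    def test_constant_offset_recovered_exactly(self):
        control = _sim("control", role="control")
        crop = _sim("crop", cooling_offset_C=2.0)
        cs = cooling_effect(control, crop)
        assert cs.mean == pytest.approx(2.0, abs=1e-12)
        assert cs.max == pytest.approx(2.0, abs=1e-12)
        assert cs.median == pytest.approx(2.0, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        a = _sim("a", role="control", noise_sd_C=0.3, seed=1)
        b = _sim("b", cooling_offset_C=1.0, noise_sd_C=0.3, seed=2)
        fwd = cooling_effect(a, b).daily_deltas
        rev = cooling_effect(b, a).daily_deltas
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_noisy_offset_within_clt_bound(self):
        delta, sd = 1.5, 0.2
        control = _sim("control", role="control", noise_sd_C=sd, seed=3)
        crop = _sim("crop", cooling_offset_C=delta, noise_sd_C=sd, seed=4)
        cs = cooling_effect(control, crop)
        n_days, per_day = cs.n_days, 96
        bound = 3 * sd * np.sqrt(2) / np.sqrt(n_days * per_day)
        assert abs(cs.mean - delta) < bound

    def test_mean_of_daily_deltas_equals_delta_of_means_on_shared_days(self):
        control = _sim("control", role="control", noise_sd_C=0.3, seed=8)
        crop = _sim("crop", cooling_offset_C=0.7, noise_sd_C=0.3, seed=9)
        cs = cooling_effect(control, crop)
        dmc = daily_means(control).means
        dmp = daily_means(crop).means
        assert cs.daily_deltas.mean() == pytest.approx(
            dmc.mean() - dmp.mean(), rel=1e-12)

    def test_no_shared_days_rejected(self):
        a = _sim("a", role="control")
        idx = pd.date_range("2023-01-01", periods=10, freq="15min")
        with pytest.raises(NoOverlapError):
            cooling_effect(a, _series(np.zeros(10), idx))


class TestDiurnalCooling:
    def test_identical_profiles_zero(self):
        s = _sim()
        assert np.allclose(diurnal_cooling(s, s, "2022-08"), 0.0)

    def test_lagged_sinusoid_matches_analytic_difference(self):
        amp, lag = 8.0, 3.0
        control = _sim("control", role="control", diurnal_amplitude_C=amp)
        crop = _sim("crop", diurnal_amplitude_C=amp, substrate_lag_hours=lag)
        deltas = diurnal_cooling(control, crop, "2022-08")
        # closed form averaged over the in-hour sample times h + {0,¼,½,¾}
        w = 2 * np.pi / 24
        t = np.arange(24)[:, None] + np.array([0, 0.25, 0.5, 0.75])
        expected = (amp * (np.cos(w * (t - 15)) - np.cos(w * (t - 15 - lag)))
                    ).mean(axis=1)
        assert np.allclose(deltas.to_numpy(), expected, atol=1e-9)

    def test_matches_profile_subtraction_oracle(self):
        control = _sim("control", role="control", noise_sd_C=0.3, seed=21)
        crop = _sim("crop", cooling_offset_C=1.0, noise_sd_C=0.3, seed=22)
        deltas = diurnal_cooling(control, crop, "2022-08")
        pc = diurnal_profile(control, "2022-08").hourly_mean
        pp = diurnal_profile(crop, "2022-08").hourly_mean
        assert np.allclose(deltas.to_numpy(), pc - pp)
        assert deltas.idxmax() in range(24)


class TestSubstrateAttenuation:
    def test_constant_offset(self):
        canopy = _sim("c15", cooling_offset_C=1.0)
        sub = _sim("sub", role="substrate", cadence_minutes=10,
                   cooling_offset_C=2.0, substrate_damping=1.0)
        cs = substrate_attenuation(sub, canopy)
        assert cs.mean == pytest.approx(1.0, abs=1e-12)

    def test_damped_zero_lag_copy_zero_attenuation(self):
        canopy = _sim("c15")
        sub = _sim("sub", role="substrate", substrate_damping=1.0,
                   substrate_lag_hours=0.0)
        cs = substrate_attenuation(sub, canopy)
        assert cs.mean == pytest.approx(0.0, abs=1e-12)

    def test_lag_and_damping_leave_daily_means_offset_only(self):
        """Daily mean of a full-period sinusoid is phase/amplitude free, so
        attenuation equals the offset difference exactly."""
        canopy = _sim("c15", cooling_offset_C=0.5)
        sub = _sim("sub", role="substrate", cadence_minutes=10,
                   cooling_offset_C=1.3, substrate_damping=0.4,
                   substrate_lag_hours=2.0)
        cs = substrate_attenuation(sub, canopy)
        assert np.allclose(cs.daily_deltas, 0.8, atol=1e-9)

    def test_warmer_substrate_days_retained_negative(self):
        canopy = _sim("c15", cooling_offset_C=2.0)
        sub = _sim("sub", role="substrate", cadence_minutes=10,
                   cooling_offset_C=1.0)
        cs = substrate_attenuation(sub, canopy)
        assert cs.mean == pytest.approx(-1.0, abs=1e-12)
        assert (cs.daily_deltas < 0).all()


class TestTukeyStats:
    def test_box_whisker_convention(self):
        idx = pd.date_range("2022-08-01", periods=11, freq="D")
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 9.0])
        from phenoroof.thermal import CoolingSummary
        cs = CoolingSummary.from_deltas(pd.Series(x, index=idx))
        assert cs.q1 == pytest.approx(np.percentile(x, 25))
        assert cs.q3 == pytest.approx(np.percentile(x, 75))
        assert 9.0 in cs.outliers          # beyond q3 + 1.5 IQR
        assert cs.whisker_hi == pytest.approx(1.0)
        assert cs.max == pytest.approx(9.0)


class TestClimateTable:
    def test_single_month_constant_mean_equals_max_equals_min(self):
        idx = pd.date_range("2022-06-01", "2022-06-08", freq="15min",
                            inclusive="left")
        t = climate_table([_series(np.full(len(idx), 20.55), idx, role="met")])
        row = t.loc[(pd.Period("2022-06"), "temperature")]
        assert row["mean"] == row["max"] == row["min"] == pytest.approx(20.55)

    def test_matches_groupby_oracle(self):
        specs = {
            "met_temp": SensorSimSpec("2022-06-20", "2022-07-10", role="met",
                                      noise_sd_C=0.5, seed=1),
            "met_wind": SensorSimSpec("2022-06-20", "2022-07-10", role="met",
                                      variable="wind", diurnal_mean_C=2.0,
                                      diurnal_amplitude_C=1.0, clip_min=0.0,
                                      noise_sd_C=0.3, seed=2),
        }
        suite = generate_sensor_suite(specs)
        t = climate_table(suite)
        for s in suite:
            dm = daily_means(s).means
            for month in dm.index.to_period("M").unique():
                sub = dm[dm.index.to_period("M") == month]
                raw = s.values[s.values.index.to_period("M") == month]
                row = t.loc[(month, s.variable)]
                assert row["mean"] == pytest.approx(sub.mean(), rel=1e-12)
                assert row["max"] == pytest.approx(raw.max())
                assert row["min"] == pytest.approx(raw.min())

    def test_months_without_complete_days_omitted(self):
        # last partial day spills into July: no complete July day
        s = _sim(start="2022-06-25", end="2022-07-01 06:00")
        t = climate_table([s])
        months = t.index.get_level_values("month").unique()
        assert pd.Period("2022-06") in months
        assert pd.Period("2022-07") not in months
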