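import numpy as np
import pandas as pd
import pytest

from cachalot import dive as dv
from cachalot.solar import solar_elevation


class TestBinDecoding:
    @pytest.mark.parametrize("index, interval", [
        (1, (0.0, 100.0)),
        (8, (700.0, 800.0)),      # a 750 m dive falls here
        (13, (1200.0, 1300.0)),
        (14, (1300.0, np.inf)),   # open-ended: a 1,860 m dive falls here
    ])
    def test_depth_intervals(self, index, interval):
        assert dv.decode_depth_bin(index) == interval

    @pytest.mark.parametrize("index, interval", [
        (1, (0.0, 5.0)),
        (7, (30.0, 35.0)),        # a 34 min dive falls here
        (14, (65.0, np.inf)),
    ])
    def test_duration_intervals(self, index, interval):
        assert dv.decode_duration_bin(index) == interval

    @pytest.mark.parametrize("bad", [0, 15, -3])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            dv.decode_depth_bin(bad)
        with pytest.raises(ValueError):
            dv.decode_duration_bin(bad)

    def test_bins_partition_positive_depths(self):
        # every positive depth maps to exactly one bin whose interval
        # contains it (upper-edge convention: decode gives (lower, upper])
        depths = np.concatenate([
            np.arange(0.5, 2000.0, 0.5),
            np.array([100.0, 200.0, 1300.0, 1300.0001, 5000.0]),
        ])
        bins = dv.encode_depth(depths)
        assert bins.min() >= 1 and bins.max() <= 14
        for d, b in zip(depths, bins):
            lo, hi = dv.decode_depth_bin(int(b))
            assert lo < d <= hi

    def test_durations_partition_positive_minutes(self):
        durations = np.concatenate([
            np.arange(0.25, 120.0, 0.25),
            np.array([5.0, 65.0, 65.0001, 600.0]),
        ])
        bins = dv.encode_duration(durations)
        for d, b in zip(durations, bins):
            lo, hi = dv.decode_duration_bin(int(b))
            assert lo < d <= hi

    def test_midpoints_and_top_bin_proxies(self):
        assert dv.bin_midpoint(1, "depth") == 50.0
        assert dv.bin_midpoint(14, "depth") == 1400.0
        assert dv.bin_midpoint(7, "duration") == 32.5
        assert dv.bin_midpoint(14, "duration") == 70.0


def brute_force_elevation(ts, lon, lat):
    """Independent low-precision solar elevation: day-angle declination and
    a sundial hour angle (equation of time from the Fourier fit)."""
    t = pd.Timestamp(ts)
    doy = t.dayofyear
    frac_year = 2 * np.pi / 365.0 * (doy - 1 + (t.hour - 12) / 24)
    decl = (0.006918 - 0.399912 * np.cos(frac_year) + 0.070257 * np.sin(frac_year)
            - 0.006758 * np.cos(2 * frac_year) + 0.000907 * np.sin(2 * frac_year)
            - 0.002697 * np.cos(3 * frac_year) + 0.00148 * np.sin(3 * frac_year))
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(frac_year)
                       - 0.032077 * np.sin(frac_year)
                       - 0.014615 * np.cos(2 * frac_year)
                       - 0.040849 * np.sin(2 * frac_year))
    minutes = t.hour * 60 + t.minute + t.second / 60
    tst = (minutes + eqtime + 4 * lon) % 1440
    ha = np.radians(tst / 4 - 180)
    phi = np.radians(lat)
    return np.degrees(np.arcsin(
        np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)))


class TestDayNight:
    def test_local_noon_and_midnight_at_study_site(self):
        # 57.5°E is ~UTC+3.8 in solar time: local solar noon ~08:10 UTC
        assert dv.classify_day_night("2016-05-15 08:10", [57.5], [-20.3]) == "day"
        assert dv.classify_day_night("2016-05-15 20:10", [57.5], [-20.3]) == "night"

    def test_matches_bruteforce_oracle(self, rng):
        times = pd.Timestamp("2015-01-01") + pd.to_timedelta(
            rng.uniform(0, 4 * 365 * 24, 1000), unit="h")
        lons = rng.uniform(-180, 180, 1000)
        lats = rng.uniform(-60, 60, 1000)
        elev = solar_elevation(times, lons, lats)
        oracle = np.array([brute_force_elevation(t, lo, la)
                           for t, lo, la in zip(times, lons, lats)])
        # the low-precision oracle is good to a fraction of a degree; the
        # day/night call may only disagree inside that twilight sliver
        np.testing.assert_allclose(elev, oracle, atol=0.7)
        away_from_terminator = np.abs(oracle) > 1.0
        agree = (elev > 0) == (oracle > 0)
        assert agree[away_from_terminator].all()

    def test_twilight_threshold_configurable(self):
        # shortly after sunset: night at 0° threshold, day at civil -6°
        ts, lon, lat = "2016-05-15 13:45", 57.5, -20.3
        elev = solar_elevation(ts, [lon], [lat])[0]
        assert -6 < elev < 0
        assert dv.classify_day_night(ts, [lon], [lat]) == "night"
        assert dv.classify_day_night(ts, [lon], [lat],
                                     twilight_elevation=-6.0) == "day"


def phase_records(day_depths, night_depths, durations=None):
    n_d, n_n = len(day_depths), len(night_depths)
    dur = durations if durations is not None else np.full(n_d + n_n, 35.0)
    return pd.DataFrame({
        "timestamp": pd.Timestamp("2016-05-01", tz="UTC"),
        "lon": 57.5, "lat": -20.3,
        "depth_m": np.r_[day_depths, night_depths],
        "duration_min": dur,
        "phase": ["day"] * n_d + ["night"] * n_n,
    })


class TestDielTest:
    def test_identical_samples_p_one(self):
        depths = np.linspace(300, 1200, 50)
        rec = phase_records(depths, depths)
        out = dv.diel_depth_test(rec)
        assert out.depth_p_value == 1.0

    def test_day_deeper_with_phase_means(self, rng):
        rec = phase_records(rng.normal(1146, 200, 100),
                            rng.normal(816, 200, 100))
        out = dv.diel_depth_test(rec)
        assert out.depth_mean_day > out.depth_mean_night
        assert out.depth_p_value < 0.001

    def test_all_shallow_rejected(self):
        rec = phase_records(np.full(10, 150.0), np.full(10, 120.0))
        with pytest.raises(ValueError):
            dv.diel_depth_test(rec)

    def test_duration_test_uses_all_dives_by_default(self, rng):
        # durations identical across phases, depths differ: duration p high
        dur = np.r_[np.full(100, 30.0), np.full(100, 30.0)]
        rec = phase_records(rng.normal(1146, 200, 100),
                            rng.normal(816, 200, 100), durations=dur)
        out = dv.diel_depth_test(rec)
        assert out.duration_p_value == 1.0
        assert out.depth_p_value < 0.001


class TestDiveSummary:
    def test_all_short(self):
        rec = phase_records(np.full(5, 500.0), np.full(5, 500.0),
                            durations=np.full(10, 5.0))
        out = dv.dive_summary(rec)
        assert out["prop_short"] == 1.0
        assert out["prop_long"] == 0.0

    def test_counting_example(self):
        rec = phase_records(np.full(3, 500.0), np.full(2, 500.0),
                            durations=np.array([5.0, 45.0, 50.0, 55.0, 70.0]))
        out = dv.dive_summary(rec)
        assert out["prop_short"] == pytest.approx(0.2)
        assert out["prop_long"] == pytest.approx(0.6)

    def test_binned_inputs_use_midpoints(self):
        rec = pd.DataFrame({
            "timestamp": pd.Timestamp("2016-05-01", tz="UTC"),
            "lon": 57.5, "lat": -20.3,
            "depth_bin": [8, 14], "duration_bin": [7, 14],
            "phase": ["day", "night"],
        })
        out = dv.dive_summary(rec)
        assert out["duration_mean"] == pytest.approx((32.5 + 70.0) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dv.dive_summary(pd.DataFrame())

    def test_generator_defaults_reproduce_diel_contract(self, dive_records):
        out = dv.diel_depth_test(dive_records)
        assert out.depth_mean_day - out.depth_mean_night > 0
        # generator phases share duration parameters: no diel duration effect
        assert out.duration_p_value > 0.05
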