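import numpy as np
import pandas as pd
import pytest

from cachalot import synthetic as syn
from cachalot.geo import haversine_km


def moran_lag1(field):
    """Lag-1 spatial autocorrelation (rook neighbours), a Moran's I variant."""
    z = field - field.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    n_pairs = z[:, :-1].size + z[:-1, :].size
    return (num / n_pairs) / z.var()


class TestEnvStack:
    def test_deterministic_given_seed(self):
        a = syn.generate_env_stack(syn.EnvFieldSpec(seed=5))
        b = syn.generate_env_stack(syn.EnvFieldSpec(seed=5))
        for name in a.layers:
            np.testing.assert_array_equal(a[name], b[name])

    def test_different_seeds_differ(self):
        a = syn.generate_env_stack(syn.EnvFieldSpec(seed=5))
        b = syn.generate_env_stack(syn.EnvFieldSpec(seed=6))
        assert not np.array_equal(a["sst"], b["sst"])

    def test_long_correlation_length_flattens_field(self):
        layers = {"sst": (1.0, (20.0, 30.0))}
        small = syn.generate_env_stack(syn.EnvFieldSpec(
            layers=layers, include_slope=False, n_islands=0, seed=2))
        layers_big = {"sst": (500.0, (20.0, 30.0))}
        big = syn.generate_env_stack(syn.EnvFieldSpec(
            layers=layers_big, include_slope=False, n_islands=0, seed=2))
        assert big["sst"].var() < 1e-3 * small["sst"].var()

    def test_autocorrelation_increases_with_correlation_length(self):
        spec = {"f1": (1.0, (0.0, 1.0)), "f5": (5.0, (0.0, 1.0))}
        stack = syn.generate_env_stack(syn.EnvFieldSpec(
            layers=spec, include_slope=False, n_islands=0, seed=9))
        assert moran_lag1(stack["f5"]) > moran_lag1(stack["f1"])

    def test_shared_latent_couples_ssh_and_bottom_temperature(self, env_stack):
        ocean = env_stack["bathymetry"] < 0
        ssh = env_stack["ssh"][ocean]
        bt = env_stack["bottom_temperature"][ocean]
        r = np.corrcoef(ssh, bt)[0, 1]
        assert r < -0.2  # thermocline-like negative coupling
        # the remaining layers stay essentially uncoupled from the drivers
        u = env_stack["u"][ocean]
        assert abs(np.corrcoef(ssh, u)[0, 1]) < 0.45

    def test_netcdf_and_dataset_round_trip(self, env_stack, tmp_path):
        from cachalot.grids import EnvStack

        back = EnvStack.from_dataset(env_stack.to_dataset())
        for name in env_stack.layers:
            np.testing.assert_array_equal(back[name], env_stack[name])
        path = tmp_path / "stack.nc"
        env_stack.to_netcdf(path)
        again = EnvStack.from_netcdf(path)
        np.testing.assert_allclose(again["sst"], env_stack["sst"])

    def test_islands_break_surface_and_ranges_respected(self, env_stack):
        assert (env_stack["bathymetry"] >= 0).sum() > 0
        assert env_stack["sst"].min() >= 22.0
        assert env_stack["sst"].max() <= 29.0

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            syn.EnvFieldSpec(extent=(55.0, 55.0, -20.0, -19.0))
        with pytest.raises(ValueError):
            syn.generate_env_stack(
                syn.EnvFieldSpec(extent=(55.0, 55.01, -20.0, -19.99),
                                 cell_size=0.08))


class TestSuitability:
    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            # all-zero coefficients are uninformative by contract
            syn.SuitabilitySpec(intercept=0.0, coefficients={"sst": 0.0})

    def test_intercept_only_gives_uniform_logistic(self, env_stack):
        suit = syn.true_suitability(env_stack, syn.SuitabilitySpec(intercept=0.0))
        np.testing.assert_allclose(suit, 0.5)

    def test_closed_form_single_layer(self):
        # intercept -1, coefficient 2 on a layer whose scaled value is 0.5
        # at mid-range cells -> logistic(0) = 0.5 there
        from cachalot.grids import EnvStack

        layer = np.array([[0.0, 1.0], [2.0, 2.0]])
        stack = EnvStack(lon=[0.0, 1.0], lat=[0.0, 1.0], layers={"x": layer})
        suit = syn.true_suitability(
            stack, syn.SuitabilitySpec(intercept=-1.0, coefficients={"x": 2.0}))
        assert suit[0, 1] == pytest.approx(0.5)  # scaled 0.5 -> eta 0
        assert suit[0, 0] == pytest.approx(1 / (1 + np.e))  # scaled 0 -> eta -1

    def test_large_coefficient_saturates_at_layer_max(self, env_stack):
        suit = syn.true_suitability(
            env_stack, syn.SuitabilitySpec(coefficients={"ssh": 80.0}))
        peak = np.unravel_index(np.argmax(env_stack["ssh"]), env_stack.shape)
        assert suit[peak] > 0.999
        assert suit.min() >= 0.0 and suit.max() <= 1.0

    def test_matches_bruteforce_cellwise_logistic(self, env_stack):
        coefs = {"ssh": 3.0, "bottom_temperature": -2.5}
        suit = syn.true_suitability(
            env_stack, syn.SuitabilitySpec(intercept=-1.0, coefficients=coefs))
        scaled = {}
        for name in coefs:
            lay = env_stack[name]
            scaled[name] = (lay - lay.min()) / (lay.max() - lay.min())
        i, j = 17, 42
        eta = -1.0 + sum(c * scaled[n][i, j] for n, c in coefs.items())
        assert suit[i, j] == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)

    def test_missing_layer_raises(self, env_stack):
        with pytest.raises(KeyError):
            syn.true_suitability(env_stack,
                                 syn.SuitabilitySpec(coefficients={"nope": 1.0}))


def implied_speeds(fixes: pd.DataFrame, true_cols=False):
    lon = fixes["true_lon" if true_cols else "lon"].to_numpy()
    lat = fixes["true_lat" if true_cols else "lat"].to_numpy()
    dt = np.diff(fixes["timestamp"].astype("int64").to_numpy()) / 3.6e12
    return haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) / dt


class TestTracks:
    def test_deterministic_and_timestamped(self, env_stack, suitability):
        spec = syn.TrackSimSpec(n_individuals=2, duration_days=5, seed=3)
        a = syn.generate_tracks(env_stack, suitability, spec)
        b = syn.generate_tracks(env_stack, suitability, spec)
        pd.testing.assert_frame_equal(a[0].fixes, b[0].fixes)
        assert a[0].fixes["timestamp"].is_monotonic_increasing

    def test_step_speed_mean_within_ten_percent(self, env_stack, suitability):
        spec = syn.TrackSimSpec(n_individuals=4, duration_days=40,
                                outlier_prob=0.0, seed=13)
        trks = syn.generate_tracks(env_stack, suitability, spec)
        speeds = np.concatenate([implied_speeds(t.fixes, true_cols=True)
                                 for t in trks])
        assert speeds.size >= 1000
        assert abs(speeds.mean() - spec.mean_speed_kmh) < 0.1 * spec.mean_speed_kmh

    def test_outlier_free_tracks_pass_speed_filter(self, env_stack, suitability):
        spec = syn.TrackSimSpec(n_individuals=3, duration_days=15,
                                outlier_prob=0.0, seed=7)
        for t in syn.generate_tracks(env_stack, suitability, spec):
            assert implied_speeds(t.fixes).max() < 7.0

    def test_bias_pulls_tracks_into_suitable_habitat(self, env_stack, suitability):
        base = dict(n_individuals=5, duration_days=30, outlier_prob=0.0, seed=17)
        unbiased = syn.generate_tracks(
            env_stack, suitability, syn.TrackSimSpec(bias_weight=0.0, **base))
        biased = syn.generate_tracks(
            env_stack, suitability, syn.TrackSimSpec(bias_weight=0.9, **base))

        def mean_suit(tracks):
            vals = []
            for t in tracks:
                r, c, ok = env_stack.nearest_index(t.fixes["true_lon"],
                                                   t.fixes["true_lat"])
                vals.append(suitability[r[ok], c[ok]])
            return np.concatenate(vals).mean()

        ocean_mean = suitability[env_stack["bathymetry"] < 0].mean()
        assert mean_suit(biased) > ocean_mean
        assert mean_suit(biased) > mean_suit(unbiased)

    def test_land_start_rejected(self, env_stack, suitability):
        land = np.unravel_index(np.argmax(env_stack["bathymetry"]), env_stack.shape)
        lonlat = (env_stack.lon[land[1]], env_stack.lat[land[0]])
        with pytest.raises(ValueError):
            syn.generate_tracks(env_stack, suitability,
                                syn.TrackSimSpec(n_individuals=1, seed=0),
                                start_lonlat=lonlat)


class TestDives:
    def test_empty_and_all_shallow(self):
        assert len(syn.generate_dive_records(
            syn.DiveSimSpec(n_records=0, seed=0))) == 0
        d = syn.generate_dive_records(
            syn.DiveSimSpec(prop_shallow=1.0, n_records=300, seed=4))
        # shallow modes sit well below the deep-dive threshold
        assert (d["depth_m"] < 400).all()

    def test_deep_mode_means_match_defaults(self):
        spec = syn.DiveSimSpec(n_records=2000, seed=8)
        d = syn.generate_dive_records(spec)
        from cachalot.dive import diel_depth_test

        s = diel_depth_test(d)
        for mean, target, n in [(s.depth_mean_day, spec.day_deep_mean, s.n_day),
                                (s.depth_mean_night, spec.night_deep_mean,
                                 s.n_night)]:
            se = spec.day_deep_sd / np.sqrt(n)
            assert abs(mean - target) < 3 * se

    def test_duration_mixture_proportions(self):
        d = syn.generate_dive_records(syn.DiveSimSpec(n_records=5000, seed=9))
        short = (d["duration_min"] < 10).mean()
        assert short == pytest.approx(0.20, abs=0.03)
        assert d["duration_min"].mean() == pytest.approx(34.0, abs=1.5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            syn.DiveSimSpec(prop_shallow=1.4)
        with pytest.raises(ValueError):
            syn.TrackSimSpec(mean_speed_kmh=-1.0)
        with pytest.raises(ValueError):
            syn.TrackSimSpec(outlier_prob=2.0)
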