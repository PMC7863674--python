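import numpy as np
import pytest

from cachalot import synthetic as syn


@pytest.fixture(scope="session")
def env_stack():
    """Small (60 x 60 cell) covariate stack shared across tests."""
    extent = (55.0, 59.8, -21.2, -16.4)
    return syn.generate_env_stack(syn.EnvFieldSpec(extent=extent, seed=11))


@pytest.fixture(scope="session")
def suitability(env_stack):
    spec = syn.SuitabilitySpec(intercept=-1.0,
                               coefficients={"ssh": 3.0, "bottom_temperature": -2.5})
    return syn.true_suitability(env_stack, spec)


@pytest.fixture(scope="session")
def sim_tracks(env_stack, suitability):
    spec = syn.TrackSimSpec(n_individuals=3, duration_days=15, seed=21)
    return syn.generate_tracks(env_stack, suitability, spec)


@pytest.fixture(scope="session")
def track_frame(sim_tracks):
    return syn.tracks_to_frame(sim_tracks)


@pytest.fixture(scope="session")
def dive_records():
    return syn.generate_dive_records(syn.DiveSimSpec(n_records=400, seed=31))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
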