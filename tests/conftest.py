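import dataclasses

import pytest
from hypothesis import settings

from fleetres import FleetResilienceModel, PriorConfig
from fleetres import synthetic

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_vessels():
    return synthetic.default_fleet(4)


@pytest.fixture(scope="session")
def demo_pings(demo_vessels):
    return synthetic.simulate_ais_tracks(demo_vessels, n_days=3, seed=1)


@pytest.fixture(scope="session")
def noiseless_params():
    """The four fleet conditions with observation noise switched off."""
    return {
        gear: dataclasses.replace(p, noise_cv=0.0)
        for gear, p in synthetic.ADRIATIC_FLEETS.items()
    }


@pytest.fixture(scope="session")
def fleet_fits(noiseless_params):
    """Full viable-pair fits of the four noiseless synthetic fleet series."""
    fits = {}
    for gear, params in noiseless_params.items():
        series = synthetic.simulate_effort_series(params)
        fits[gear] = FleetResilienceModel(series, prior=PriorConfig(seed=1)).fit()
    return fits
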