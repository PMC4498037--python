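import dataclasses

import numpy as np
import pytest

import fertisim as fs
from fertisim.calibration import Sampling, TrialObservations


@pytest.fixture(scope="session")
def med_weather():
    """One bundled synthetic Mediterranean season (fixed documented seed)."""
    return fs.scenario_weather()


@pytest.fixture()
def default_config():
    return fs.SimulationConfig()


@pytest.fixture(scope="session")
def baseline_season(med_weather):
    return fs.run_season(fs.SimulationConfig(), med_weather)


def make_potential_trial(trial_id, beta1_factor, seed, growth=None, thermal=None,
                         dats=(20, 35, 50, 65, 80, 95, 110)):
    """A synthetic unstressed trial: observed biomass follows the logistic of
    a 'true' parameter set whose asymptote is the baseline one scaled by
    ``beta1_factor``; thermal time is accrued from seeded synthetic weather."""
    growth = growth or fs.GrowthParams()
    thermal = thermal or fs.ThermalParams()
    weather = fs.generate_synthetic_weather(
        fs.Site(latitude=41.53, altitude=75), fs.mediterranean_profile(), 130, seed
    )
    gdd = np.cumsum([fs.thermal_time(d, thermal) for d in weather])
    true = dataclasses.replace(growth, beta1=growth.beta1 * beta1_factor)
    samplings = [
        Sampling(dat=d, tt_cum=float(gdd[d - 1]),
                 sdw_obs=fs.potential_sdw(float(gdd[d - 1]), true))
        for d in dats
    ]
    return TrialObservations(trial_id, samplings, weather=list(weather))


@pytest.fixture(scope="session")
def self_consistent_check_params():
    """Growth-check polynomials calibrated on trials generated exactly by the
    baseline parameters (CheckPO = 1 everywhere)."""
    trials = [make_potential_trial(f"s{i}", 1.0, 200 + i) for i in range(4)]
    return fs.calibrate_sdwcheck(trials, fs.GrowthParams(), fs.ThermalParams())


@pytest.fixture(scope="session")
def recovery_check_params():
    """Growth-check polynomials calibrated on trials whose true asymptote was
    scaled by factors spanning under- and over-prediction."""
    factors = [0.8, 0.9, 1.0, 1.15, 1.3]
    trials = [
        make_potential_trial(f"t{i}", f, 100 + i) for i, f in enumerate(factors)
    ]
    return fs.calibrate_sdwcheck(trials, fs.GrowthParams(), fs.ThermalParams())
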