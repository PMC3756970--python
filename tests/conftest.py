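import numpy as np
import pytest
from hypothesis import settings

import invadrift as iv
from invadrift.environment import EnvironmentStack, GridSpec
from invadrift.experiments import run_replicates

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

#: frozen study conditions for the replicate-ensemble tests: a sequence-rich
#: life-history regime (larval mortality at the low end of the documented
#: 0.01-0.69 1/d range, two spawning events per monthly cycle, persistent
#: founder population) on the 60x60 synthetic shelf sea
SCENARIO = dict(propagule_mortality=0.05, founder_immortal=True, spawns_per_cycle=2)
SCENARIO_ORIGIN = (26.217, -80.083)
SCENARIO_MONTHS = 78
SCENARIO_REPS = 20
SCENARIO_SEED = 7
ENV_SEED = 1


def make_uniform_stack(nrows=20, ncols=20, speed=0.0, direction=0.0,
                       sst=25.0, chl=1.0, depth=20.0,
                       lat_min=-1.0, lon_min=0.0, resolution=6.0,
                       land_mask=None) -> EnvironmentStack:
    """Spatially uniform stack for analytic engine tests."""
    grid = GridSpec(lat_min=lat_min, lat_max=lat_min + nrows * resolution / 60.0,
                    lon_min=lon_min, lon_max=lon_min + ncols * resolution / 60.0,
                    resolution=resolution)
    assert grid.n_rows == nrows and grid.n_cols == ncols
    shape = (nrows, ncols)
    if land_mask is None:
        land_mask = np.zeros(shape, dtype=bool)
    return EnvironmentStack(
        grid=grid,
        current_speed=np.full((12, *shape), float(speed)),
        current_direction=np.full((12, *shape), float(direction)),
        sst=np.full((12, *shape), float(sst)),
        chlorophyll=np.full((12, *shape), float(chl)),
        depth=np.full(shape, float(depth)),
        land_mask=land_mask,
    )


@pytest.fixture(scope="session")
def synth_stack():
    return iv.generate_synthetic_environment(seed=ENV_SEED)


@pytest.fixture(scope="session")
def default_config():
    return iv.ModelConfig()


@pytest.fixture(scope="session")
def scenario_config():
    return iv.ModelConfig(**SCENARIO)


@pytest.fixture(scope="session")
def scenario_runs(synth_stack, scenario_config):
    """20 replicate 78-month runs of the frozen validation scenario."""
    return run_replicates(scenario_config, synth_stack, SCENARIO_ORIGIN,
                          SCENARIO_MONTHS, SCENARIO_REPS, seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def null_runs(synth_stack):
    """10 random-contagion null realizations from the scenario origin."""
    return [iv.run_null_model(synth_stack, SCENARIO_ORIGIN, seed=1000 + i,
                              max_cycles=200)
            for i in range(10)]


@pytest.fixture(scope="session")
def uniform_jet_stack():
    """Uniform northward current at 1 m/s, everything habitable."""
    return make_uniform_stack(nrows=40, ncols=20, speed=1.0, direction=0.0)
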