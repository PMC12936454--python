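import numpy as np
import pandas as pd
import pytest

import agrocycle as ac


@pytest.fixture(scope="session")
def config():
    return ac.default_config()


@pytest.fixture(scope="session")
def plans(config):
    return {name: ac.build_rotation(name, config) for name in ("BAU", "Vegan", "ICLS")}


@pytest.fixture(scope="session")
def small_tables(config):
    """One small but complete pipeline run shared across test modules."""
    cfg = ac.default_config()
    cfg["run"].update(
        n_sites=6, scenarios=["historical", "+4C_MPI"], seed=11, metric="gwpstar"
    )
    return ac.run_pipeline(cfg)


@pytest.fixture(scope="session")
def one_site(config):
    return ac.generate_sites(1, seed=3, config=config)[0]


@pytest.fixture(scope="session")
def hist_weather(one_site, config):
    scen = ac.scenario_by_name("historical")
    return ac.generate_weather(one_site, scen, 24, seed=3, config=config)
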