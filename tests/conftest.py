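import pytest

from fcmsim import SimulationConfig, build_iopd_fixture, run_replicates, standard_recipes


@pytest.fixture(scope="session")
def iopd_net():
    return build_iopd_fixture()


@pytest.fixture(scope="session")
def recipes(iopd_net):
    return standard_recipes(iopd_net)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def model_profiles(iopd_net, recipes, sim_config):
    """Steady-state replicate profiles of the four study models."""
    return {
        name: run_replicates(iopd_net, r.clamps(), sim_config, n_replicates=3)
        for name, r in recipes.items()
    }
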