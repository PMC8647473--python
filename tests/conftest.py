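import pytest
from hypothesis import settings

import caproflux as cf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> cf.Registry:
    return cf.Registry.default()


@pytest.fixture(scope="session")
def cstr_config() -> cf.ReactorConfig:
    return cf.ReactorConfig()


@pytest.fixture(scope="session")
def nonextractive_run(cstr_config):
    """A zero-noise non-extractive CSTR run reaching steady state."""
    return cf.simulate_cstr(cf.SimParams(), cstr_config, t_end=80.0, dt_out=0.5)


@pytest.fixture(scope="session")
def abiotic_batch_run():
    """Closed two-phase bottle, no biomass: pure partitioning dynamics."""
    params = cf.SimParams(
        x0_emeq_per_L=0.0, kd={"n-caproate": 2.5}, ka={"n-caproate": 5.0}
    )
    return cf.simulate_batch(
        params,
        v_aq=0.04,
        v_org=0.008,
        t_end=20.0,
        dt_out=0.25,
        initial_mM={"n-caproate": 6.5 / 116.16 * 1000.0},
    )
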