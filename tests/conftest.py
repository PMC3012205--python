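import pytest

from fertbias import SimulationParams, SSMParams, simulate_population


@pytest.fixture
def worked_example_params():
    """The headline parameter combination: r=3, d=1, W=1, symmetric prior."""
    return SSMParams(r=3.0, d=1.0, W=1.0, p_low=0.5)


@pytest.fixture
def sim_params_factory():
    """SimulationParams with convenient test defaults, overridable per call."""

    def make(**overrides):
        ssm_overrides = {"r": 3.0, "d": 1.0, "W": 1.0, "p_low": 0.5}
        for key in list(overrides):
            if key in ssm_overrides:
                ssm_overrides[key] = overrides.pop(key)
        defaults = dict(
            ssm=SSMParams(**ssm_overrides),
            n_families=2000,
            prop_schizotypal=0.5,
            family_size=5,
            p_diag_high=0.05,
            base_mean_offspring=2.0,
            seed=12345,
        )
        defaults.update(overrides)
        return SimulationParams(**defaults)

    return make


@pytest.fixture
def medium_population(sim_params_factory):
    """A 10k-family population at the worked-example parameters."""
    return simulate_population(sim_params_factory(n_families=10000, seed=777))
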