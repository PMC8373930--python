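import numpy as np
import pytest

from foldstab import (
    BaselineParams,
    ExperimentDesign,
    ThermoParams,
    reference_params,
    simulate_dataset,
)

WT = ThermoParams(t_m=352.3, dh_m=-322.0, dcp=-4.3, m_value=8.2)
I57A = ThermoParams(t_m=333.1, dh_m=-269.0, dcp=-5.4, m_value=11.6)


@pytest.fixture(scope="session")
def wt_params():
    return WT


@pytest.fixture(scope="session")
def i57a_params():
    return I57A


@pytest.fixture(scope="session")
def default_baselines():
    return BaselineParams(1000.0, -2.0, 0.0, 600.0, -1.0, 20.0)


@pytest.fixture(scope="session")
def coarse_design():
    """Published design at a 1 degC read spacing (faster fits, same grid span)."""
    return ExperimentDesign(temperature_step=1.0, seed=1)


@pytest.fixture(scope="session")
def noise_free_design():
    return ExperimentDesign(temperature_step=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def wt_noise_free(default_baselines, noise_free_design):
    return simulate_dataset(
        reference_params("wild-type"),
        default_baselines,
        noise_free_design,
        variant_label="wild-type",
    )


@pytest.fixture(scope="session")
def wt_noisy(default_baselines, coarse_design):
    return simulate_dataset(
        reference_params("wild-type"),
        default_baselines,
        coarse_design,
        variant_label="wild-type",
    )


def random_params(rng: np.random.Generator) -> ThermoParams:
    """A random plausible cooperative folder (folding sign convention)."""
    return ThermoParams(
        t_m=float(rng.uniform(320.0, 370.0)),
        dh_m=float(rng.uniform(-450.0, -100.0)),
        dcp=float(rng.uniform(-7.0, -0.5)),
        m_value=float(rng.uniform(4.0, 12.0)),
    )
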