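import numpy as np
import pytest

from rumenkin import TrialConfig, default_calibration, generate_trial


@pytest.fixture(scope="session")
def zero_noise_config():
    return TrialConfig(seed=11, noise_log_conc_sd=0.0, balance_cv=0.0,
                       cow_re_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise_trial(zero_noise_config):
    return generate_trial(zero_noise_config, default_calibration())


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial(TrialConfig(seed=5), default_calibration())


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
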