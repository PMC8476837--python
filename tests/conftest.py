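import numpy as np
import pytest

from metabmr.io import HarmonizedSet
from metabmr.pipeline import load_study, run_batch
from metabmr.simulate import make_fixture_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def h_two():
    """Hand-checkable two-instrument set: beta=2, Q=2."""
    return HarmonizedSet.from_arrays(gamma=[1.0, 1.0], sigma_x=[0.1, 0.1],
                                     Gamma=[1.0, 3.0], sigma_y=[1.0, 1.0])


@pytest.fixture
def h_line():
    """Three instruments exactly on Gamma = 0.1 + 0.5 * gamma."""
    return HarmonizedSet.from_arrays(gamma=[1.0, 2.0, 3.0],
                                     sigma_x=[0.1, 0.1, 0.1],
                                     Gamma=[0.6, 1.1, 1.6],
                                     sigma_y=[1.0, 1.0, 1.0])


def random_harmonized(rng, J=10, beta=0.3):
    gamma = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
    sigma_x = rng.uniform(0.01, 0.05, J)
    sigma_y = rng.uniform(0.005, 0.05, J)
    Gamma = beta * gamma + rng.normal(0, sigma_y)
    return HarmonizedSet.from_arrays(gamma, sigma_x, Gamma, sigma_y)


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """The small planted batch study, written once per test session."""
    out = tmp_path_factory.mktemp("study")
    return make_fixture_study(scale="small", seed=7, out_dir=str(out))


@pytest.fixture(scope="session")
def fixture_batch(fixture_study):
    """The full batch run over the fixture study (shared across tests)."""
    exposures, outcome, panel, exclusion, cfg = load_study(
        fixture_study.config_path)
    result = run_batch(exposures, outcome, panel=panel, exclusion=exclusion,
                       config=cfg)
    return fixture_study, result
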