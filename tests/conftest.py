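import warnings

import pytest

from rapskill.dhglm import ConvergenceWarning
from rapskill.preprocess import build_report
from rapskill.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-fight synthetic dataset shared by read-only tests."""
    return generate_dataset(GeneratorConfig(n_fights=40, seed=2024))


@pytest.fixture(scope="session")
def small_report(small_dataset):
    return build_report(small_dataset.fights, small_dataset.pois)


@pytest.fixture()
def quiet_convergence():
    """Silence expected non-convergence warnings in short MCMC runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield
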