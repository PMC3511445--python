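import numpy as np
import pytest

from erkensemble.ensemble import FitProblem
from erkensemble.mek_input import MekInputParams, fit_mek_timecourse
from erkensemble.synthetic import generate_dataset, paper_like_config


@pytest.fixture(scope="session")
def default_dataset():
    """One noisy paper-like synthetic dataset plus its ground truth."""
    return generate_dataset(paper_like_config(seed=1))


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Noise-free variant: means equal the model output exactly."""
    return generate_dataset(paper_like_config(seed=1, noise_cv=0.0))


@pytest.fixture(scope="session")
def default_problem(default_dataset):
    dataset, _ = default_dataset
    inputs = {
        c: fit_mek_timecourse(dataset, c) for c in dataset.conditions_with("pERK")
    }
    return FitProblem(dataset, inputs)


@pytest.fixture(scope="session")
def noisefree_problem(noisefree_dataset):
    dataset, _ = noisefree_dataset
    inputs = {
        c: fit_mek_timecourse(dataset, c) for c in dataset.conditions_with("pERK")
    }
    return FitProblem(dataset, inputs)


def theta_from_truth(truth):
    """Ground-truth record -> natural-unit parameter vector."""
    from erkensemble.erk_model import PARAM_NAMES

    base = truth["erk_params_true"]
    return np.array(
        [base[n] for n in PARAM_NAMES if n != "phi"] + [truth["phi_true"]]
    )


@pytest.fixture
def mek_params():
    return MekInputParams(m0=0.1, amplitude=0.8, tau_rise=8.0, tau_decay=90.0)
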