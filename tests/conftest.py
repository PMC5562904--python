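import warnings

import numpy as np
import pytest

import phasecoint as pc
from phasecoint.experiments import winfree_spec

# the amplitude-excursion warning is an expected feature of the study DGP
warnings.filterwarnings(
    "ignore", message="amplitude reached a non-positive value", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def indep_traj():
    """One study-condition trajectory of the independent three-oscillator system."""
    return pc.simulate_winfree(winfree_spec("independent", seed=101))


@pytest.fixture(scope="session")
def uni_traj():
    """One study-condition trajectory of the uni-directionally coupled system."""
    return pc.simulate_winfree(winfree_spec("unidirectional", seed=202))


@pytest.fixture(scope="session")
def full_traj():
    """One study-condition trajectory of the fully coupled system."""
    return pc.simulate_winfree(winfree_spec("full", seed=303))


@pytest.fixture(scope="session")
def ou_uni_traj():
    """Exact-transition sample of the degenerate-amplitude model under
    uni-directional coupling (the correctly specified VECM)."""
    alpha = np.array([[-0.5], [0.0], [0.0]])
    beta = np.array([[1.0], [-1.0], [0.0]])
    return pc.simulate_ou_phase_exact(
        alpha @ beta.T, [0.75, 1.0, 1.0], np.ones(3), 0.1, 2000,
        [0.0, np.pi / 2, np.pi], seed=404,
    )
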