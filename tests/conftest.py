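import numpy as np
import pytest

from numbayes import (
    AncestralEvaluator,
    ObserverSpec,
    make_training_distribution,
    sample_stimulus_sequence,
    simulate_estimation_session,
)


@pytest.fixture(scope="session")
def narrow():
    return make_training_distribution("narrow")


@pytest.fixture(scope="session")
def medium():
    return make_training_distribution("medium")


@pytest.fixture(scope="session")
def quadrimodal():
    return make_training_distribution("quadrimodal")


@pytest.fixture(scope="session")
def narrow_session(narrow):
    """A 400-trial Dirichlet+sample observer session on the narrow design."""
    spec = ObserverSpec(sigma=0.22, prior_update="dirichlet", decision="sample")
    stimuli = sample_stimulus_sequence(narrow, 400, seed=11)
    return simulate_estimation_session(spec, stimuli, seed=12)


@pytest.fixture(scope="session")
def narrow_evaluator(narrow_session):
    return AncestralEvaluator(narrow_session, sigma=0.22, mc_samples=500, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
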