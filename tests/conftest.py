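import numpy as np
import pytest

import cathmap as cm

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def encoder():
    return cm.OctamerEncoder().fit()


@pytest.fixture(scope="session")
def rule():
    return cm.make_rule(seed=11)


@pytest.fixture(scope="session")
def small_library(rule):
    """A small but trainable synthetic library (shared across tests)."""
    examples, truth, proteins = cm.generate_training_library(
        rule, n_proteins=8, protein_length=120, seed=11)
    return examples, truth, proteins


@pytest.fixture(scope="session")
def small_model(small_library):
    """One ensemble model fitted on the small library (expensive; share it)."""
    examples, _, _ = small_library
    model = cm.DipeptideEnsembleClassifier(random_state=11, n_members=3)
    model.fit(examples, [ex.label for ex in examples])
    return model


@pytest.fixture
def rng():
    return np.random.RandomState(0)


def random_octamer(rng, dipeptide=None):
    o = "".join(rng.choice(list(AMINO_ACIDS), 8))
    if dipeptide:
        o = o[:3] + dipeptide + o[5:]
    return o
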