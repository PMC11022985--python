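"""Shared fixtures.

The uncertainty study trains 2 x 10 tiny ensemble members and is by far the
most expensive fixture; it is session-scoped and shared by every test that
probes trained-model behaviour.
"""

import pytest
from hypothesis import settings

from soluens.experiments import run_uncertainty_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from soluens.synthetic import SyntheticSpec, generate_synthetic_corpus


@pytest.fixture(scope="session")
def synthetic_corpus_2000():
    """The reference heteroscedastic corpus: 2000 molecules, fixed seed."""
    return generate_synthetic_corpus(SyntheticSpec(n_molecules=2000, seed=11))


@pytest.fixture(scope="session")
def uncertainty_study():
    """Tiny-member pools trained on the reference corpus (fixed seeds)."""
    return run_uncertainty_study(corpus_seed=11, train_seed=2024)
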