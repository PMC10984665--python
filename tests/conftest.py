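import numpy as np
import pytest

from masldnlp import Annotator
from masldnlp.synthetic import GenerationSpec, generate_corpus


@pytest.fixture(scope="session")
def annotator() -> Annotator:
    return Annotator()


@pytest.fixture(scope="session")
def canonical_corpus():
    """A small deterministic corpus with no adversarial templates."""
    spec = GenerationSpec(n_reports=300, seed=11, adversarial_rate=0.0)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def adversarial_corpus():
    """A corpus drawn entirely from hard templates (ranges, chains, scopes)."""
    spec = GenerationSpec(n_reports=300, seed=13, adversarial_rate=1.0)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
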