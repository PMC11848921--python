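import numpy as np
import pytest

from pnaseq.chem import DEFAULT_REGISTRY
from pnaseq.fixtures import random_template
from pnaseq.simulate import design_primer_set


@pytest.fixture
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template(rng):
    """A seeded 22-nt d-DNA template."""
    return random_template(rng, 22)


@pytest.fixture
def primers(template):
    return design_primer_set(template)
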