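import numpy as np
import pytest

from mfremotif.enzymes import MotifModel
from mfremotif.sequence import ReferenceGenome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ccwgg():
    """The Dcm motif: palindromic CCWGG, second C methylated, x = -2."""
    return MotifModel.palindromic("CCWGG", 1)


@pytest.fixture
def uniform_background():
    return {b: 0.25 for b in "ACGT"}


def random_genome(rng, length=10_000, gc=0.5, name="chr"):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    return ReferenceGenome([(name, seq)])


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, length=10_000)
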