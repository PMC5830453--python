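import numpy as np
import pytest
from hypothesis import settings

from trapcode.simulate import make_call

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def usv_call():
    """A six-syllable synthetic pup-call annotation (3 s playback unit)."""
    return make_call("USV", 6)


@pytest.fixture
def calls_six():
    """Six call stimuli with at least six syllables each, as in the full design."""
    names = ["USV", "USV2", "USVB6", "USVflip", "maleUSV", "WC"]
    return {n: make_call(n, 6) for n in names}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
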