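import numpy as np
import pytest

from plmkit.alphabet import CANONICAL_AA
from plmkit.fixtures import synth_tiny_model, tiny_config

AA = list(CANONICAL_AA)


def random_protein(rng, n):
    return "".join(rng.choice(AA, size=n))


@pytest.fixture(scope="session")
def rotary_model():
    return synth_tiny_model(tiny_config("rotary"), seed=11)


@pytest.fixture(scope="session")
def learned_model():
    return synth_tiny_model(tiny_config("learned", max_positions=128), seed=11)


@pytest.fixture(scope="session")
def swiglu_model():
    return synth_tiny_model(tiny_config("rotary", activation="swiglu"), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_corpus():
    r = np.random.default_rng(42)
    return [random_protein(r, int(n)) for n in r.integers(10, 60, size=20)]
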