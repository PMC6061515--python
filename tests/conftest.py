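import numpy as np
import pytest

from altchip import ideal_spectrum

# small hand-traceable instance used across the suite
TOY_TARGET = "ACGTACGG"
TOY_K = 3
TOY_PREFIX = TOY_TARGET[: 2 * TOY_K]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def toy_spectrum():
    return ideal_spectrum(TOY_TARGET, TOY_K)


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)
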