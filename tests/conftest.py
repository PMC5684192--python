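import numpy as np
import pytest

from temra_repertoire import Repertoire


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rep():
    return Repertoire("d1", "TEM", {"CASSF": 12, "CARGF": 10, "CSARF": 9,
                                    "CAWSF": 1})


def random_repertoire(rng, n_clones, max_count=50, donor="d1", subset="TEM"):
    """Random repertoire with distinct synthetic clonotype keys."""
    counts = rng.integers(1, max_count + 1, size=n_clones)
    clones = {f"CAS{i}F".replace(str(i), _enc(i)): int(c)
              for i, c in enumerate(counts)}
    return Repertoire(donor, subset, clones)


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _enc(i: int) -> str:
    # encode an integer as amino-acid letters so keys are valid CDR3s
    s = ""
    while True:
        s += _AA[i % 20]
        i //= 20
        if i == 0:
            return s
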