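import numpy as np
import pytest

from knotminer.ick_domains import scan_ick, split_domains
from knotminer.synthetic_data import xt3a_scaffold


@pytest.fixture(scope="session")
def xt3a():
    """The 82-residue double-knot fixture scaffold."""
    return xt3a_scaffold()


@pytest.fixture(scope="session")
def xt3a_hits(xt3a):
    return scan_ick(xt3a)


@pytest.fixture(scope="session")
def xt3a_domains(xt3a, xt3a_hits):
    domains, linkers = split_domains(xt3a, xt3a_hits)
    return domains


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
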