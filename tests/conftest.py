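import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epiwalsh import GenotypePhenotypeMap

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def binary_genotypes(L: int) -> list[str]:
    return ["".join(bits) for bits in itertools.product("01", repeat=L)]


def binary_map(L: int, phenotypes, stdevs=0.0, n=1) -> GenotypePhenotypeMap:
    return GenotypePhenotypeMap.from_arrays(
        binary_genotypes(L), phenotypes, stdevs=stdevs, n=n
    )


@pytest.fixture
def toy_map() -> GenotypePhenotypeMap:
    """Two-site map with negative epistasis: P00=0, P01=2, P10=1, P11=2."""
    return GenotypePhenotypeMap.from_arrays(
        ["00", "01", "10", "11"], [0.0, 2.0, 1.0, 2.0]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
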