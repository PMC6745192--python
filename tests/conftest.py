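import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atbias.types import GeneticCode

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code11() -> GeneticCode:
    """Bacterial/plastid genetic code (standard three-stop set)."""
    return GeneticCode.from_ncbi(11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_dna(rng: np.random.Generator, n: int,
               p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])
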