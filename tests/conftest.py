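import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "delmap",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("delmap")


@pytest.fixture
def toy_layout():
    """Single 200-unit chromosome with the centromere at 100."""
    from delmap.genome import Chromosome, GenomeLayout

    return GenomeLayout((Chromosome("chr", 200, 100),))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
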