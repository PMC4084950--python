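import numpy as np
import pytest

from crispr_di.community import Community, HostStrain, ViralStrain
from crispr_di.fixtures import make_random_community


@pytest.fixture
def rng():
    return np.random.default_rng(20240707)


@pytest.fixture
def even_distributed_triplet():
    """Two equally abundant hosts immune to one virus via different spacers."""
    h1 = HostStrain(1, (1,), 0.5)
    h2 = HostStrain(2, (2,), 0.5)
    v = ViralStrain(1, (1, 2, 3), 1.0)
    return Community((h1, h2), (v,))


@pytest.fixture
def random_communities(rng):
    return [make_random_community(rng) for _ in range(120)]
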