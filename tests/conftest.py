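import numpy as np
import pytest

from terscope.contact_map import ContactMap, scn_normalize
from terscope.synthetic_data import SyntheticMapSpec, gen_contact_map


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_normalized_map():
    """A 200-bin (1 Mb) homogeneous balanced map used across modules."""
    spec = SyntheticMapSpec(chrom_length=1_000_000, lambda_bp=100_000,
                            depth=1000)
    return scn_normalize(gen_contact_map(spec, seed=42))


@pytest.fixture
def random_symmetric_map(rng):
    """Small random positive symmetric ContactMap (raw)."""
    m = rng.poisson(20, size=(30, 30)).astype(float)
    m = m + m.T
    return ContactMap(m, bin_size=5000, circular=True, state="raw")
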