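import numpy as np
import pytest

from litrswitch.network import LITRConfig, build_litr_network
from litrswitch.reduced import ReducedGeneParams


@pytest.fixture(scope="session")
def reference_gene():
    return ReducedGeneParams.reference()


@pytest.fixture(scope="session")
def litr_net_plain():
    """One copy of each gene, no inducers."""
    return build_litr_network(LITRConfig(n_lacI=1, n_tetR=1, iptg=0.0, dox=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160606)
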