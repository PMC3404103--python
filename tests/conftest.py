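import numpy as np
import pytest

from sfcollapse import synthgen


@pytest.fixture(scope="session")
def reference_pair():
    """Conductive/collapsed idealized filter pair with known span."""
    return synthgen.make_reference_pair(collapse_displacement=1.0, d_cb=10.0)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20120724)
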