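import numpy as np
import pytest

from sh2bind.panel import load_panel


@pytest.fixture(scope="session")
def table2():
    """Packaged published peptide panel (13 GHR + 10 EpoR records)."""
    return load_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
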