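import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from statescape import build_csf_hamiltonian
from statescape.fixtures import DEFAULT_SEED


@pytest.fixture(scope="session")
def h2():
    """CSF Hamiltonians at the bond lengths used throughout the suite."""
    return {R: build_csf_hamiltonian(R) for R in (1.437707, 2.0, 3.0, 6.0)}


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
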