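import numpy as np
import pytest

from coilslab.build import build_protein
from coilslab.model import cc_protein, default_forcefield


@pytest.fixture(scope="session")
def dimer_ff():
    return default_forcefield("dimer")


@pytest.fixture(scope="session")
def three_coil_dimer():
    return cc_protein(3, "dimer")


@pytest.fixture(scope="session")
def two_coil_system(dimer_ff):
    """2-coil-1-linker chain (32/25/32 residues): 89 beads."""
    return build_protein(cc_protein(2, "dimer"), dimer_ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
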