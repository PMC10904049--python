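import numpy as np
import pytest

from radmem.electro import MembraneModel
from radmem.fretflow import SpectralParams
from radmem.seqcharge import ProteinSequence


@pytest.fixture
def membrane() -> MembraneModel:
    """The cytoplasmic-leaflet reference model: -35 mV, 150 mM, 25 C."""
    return MembraneModel(v0=-35.0, ionic_strength=0.150,
                         temperature=298.15, relative_permittivity=78.5)


@pytest.fixture
def spectral() -> SpectralParams:
    return SpectralParams(r_d=0.1, r_a=0.05, g_factor=2.0, f_d=1.0, f_a=1.0)


@pytest.fixture
def random_protein() -> ProteinSequence:
    rng = np.random.default_rng(42)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    residues = "".join(rng.choice(aas, size=60))
    return ProteinSequence(id="rand60", residues=residues,
                           regions={"head": (1, 21), "tail": (41, 61)})
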