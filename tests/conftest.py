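import numpy as np
import pytest
from hypothesis import settings

from fragsense import fixture_structures, parse_structure

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return fixture_structures()


#: diverse molecules with <= 12 heavy atoms for exhaustive MCS checks
SMALL_MOLECULE_SMILES = {
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "pyrimidine": "c1cncnc1",
    "thiophene": "c1ccsc1",
    "furan": "c1ccoc1",
    "pyrrole": "c1cc[nH]c1",
    "indole": "c1ccc2[nH]ccc2c1",
    "phenol": "Oc1ccccc1",
    "toluene": "Cc1ccccc1",
    "piperidine": "C1CCNCC1",
    "trigonelline": "C[n+]1cccc(C(=O)[O-])c1",
    "tryptamine": "NCCc1c[nH]c2ccccc12",
}


@pytest.fixture(scope="session")
def small_molecules():
    return {name: parse_structure(smi, name) for name, smi in SMALL_MOLECULE_SMILES.items()}


def bit_vector(rng: np.random.Generator, length: int, density: float = 0.3) -> np.ndarray:
    return rng.random(length) < density
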