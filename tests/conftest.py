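import numpy as np
import pytest

from qsarscreen.fingerprints import FingerprintConfig, fingerprint_matrix
from qsarscreen.synthetic import SyntheticSpec, generate_dataset

#: small, structurally varied SMILES panel used for fingerprint parity checks
SMILES_PANEL = [
    "c1ccccc1",
    "C1=CC=CC=C1",
    "CCO",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "O=C(N)c1ccc(Cl)cc1",
    "C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "c1ccc2ncncc2c1",
    "CC(=O)Nc1ccc(O)cc1",
    "OC(=O)c1ccccc1O",
    "ClC(Cl)Cl",
    "N#Cc1ccccc1",
    "CCCCCCCC",
    "O=S(=O)(N)c1ccccc1",
    "c1ccc(-c2ccccc2)cc1",
    "C1CCNCC1",
    "CC(N)C(=O)O",
    "FC(F)(F)c1ccccc1",
    "O=C1CCCCC1",
]


@pytest.fixture(scope="session")
def small_dataset():
    """120-compound synthetic dataset for fast structural/model tests."""
    return generate_dataset(SyntheticSpec(n_compounds=120), seed=20)


@pytest.fixture(scope="session")
def small_xy(small_dataset):
    keys = [c.structure_key for c in small_dataset]
    y = np.array([c.pchembl for c in small_dataset])
    matrix, failures = fingerprint_matrix(keys, FingerprintConfig())
    assert not failures
    return keys, matrix.matrix.astype(float), y, matrix
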