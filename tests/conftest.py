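import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memstab import PeptideID

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def peptide() -> PeptideID:
    """An interfacial TM4a-b-like peptide (positions 174-185, charge 2)."""
    return PeptideID(sequence="GLIVLSMAQTLE", start=174, end=185, charge=2)


@pytest.fixture
def melt_temperatures() -> np.ndarray:
    """Pre-pulse temperature grid of the HDX melt experiments (degC)."""
    return np.arange(20.0, 65.1, 5.0)


@pytest.fixture
def sec_temperatures() -> np.ndarray:
    """Dense SEC melt grid bracketing both transitions."""
    return np.arange(4.0, 66.0, 1.0)


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.200   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       6.000   1.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU A   3      11.000   1.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-residue single-chain structure with hand-set distances.

    Closest heavy-atom separations: res1-res2 = 4.0 A (CB to CA-2),
    res2-res3 = 5.0 A, res1-res3 = 9.0 A.
    """
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path
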