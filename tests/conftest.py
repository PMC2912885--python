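import numpy as np
import pytest

from corefit.geometry import RigidTransform, rotation_angle

# --- handcrafted PDB fixtures (written to tmp_path by the fixtures below) ---

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY A   2       8.121   5.022  -4.421  1.00  0.00           C
ATOM      4  CA  SER A   3       5.220   3.907  -6.709  1.00  0.00           C
ATOM      5  O   SER A   3       4.000   3.000  -6.000  1.00  0.00           O
END
"""

# second model rigidly shifted by +1 on x
TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA  GLY A   2       8.121   5.022  -4.421  1.00  0.00           C
ATOM      3  CA  SER A   3       5.220   3.907  -6.709  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1      12.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA  GLY A   2       9.121   5.022  -4.421  1.00  0.00           C
ATOM      3  CA  SER A   3       6.220   3.907  -6.709  1.00  0.00           C
ENDMDL
END
"""

# residue 2 carries an altloc pair; B has the higher occupancy
ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA AGLY A   2       8.121   5.022  -4.421  0.30  0.00           C
ATOM      3  CA BGLY A   2       8.500   5.100  -4.500  0.70  0.00           C
ATOM      4  CA  SER A   3       5.220   3.907  -6.709  1.00  0.00           C
END
"""

# model 2 misses residue 2
ENSEMBLE_GAP_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA  GLY A   2       8.121   5.022  -4.421  1.00  0.00           C
ATOM      3  CA  SER A   3       5.220   3.907  -6.709  1.00  0.00           C
ATOM      4  CA  LEU A   4       3.220   2.907  -3.709  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1      11.739   6.171  -5.247  1.00  0.00           C
ATOM      2  CA  SER A   3       5.320   4.007  -6.809  1.00  0.00           C
ATOM      3  CA  LEU A   4       3.320   3.007  -3.809  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1      11.539   5.971  -5.047  1.00  0.00           C
ATOM      2  CA  GLY A   2       8.021   4.922  -4.321  1.00  0.00           C
ATOM      3  CA  SER A   3       5.120   3.807  -6.609  1.00  0.00           C
ATOM      4  CA  LEU A   4       3.120   2.807  -3.609  1.00  0.00           C
ENDMDL
END
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture
def minimal_pdb(tmp_path):
    return _write(tmp_path, "minimal.pdb", MINIMAL_PDB)


@pytest.fixture
def two_model_pdb(tmp_path):
    return _write(tmp_path, "two_model.pdb", TWO_MODEL_PDB)


@pytest.fixture
def altloc_pdb(tmp_path):
    return _write(tmp_path, "altloc.pdb", ALTLOC_PDB)


@pytest.fixture
def ensemble_gap_pdb(tmp_path):
    return _write(tmp_path, "ensemble_gap.pdb", ENSEMBLE_GAP_PDB)


# --- helpers ---

def rotation_error_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees."""
    return rotation_angle(RigidTransform(np.asarray(R1) @ np.asarray(R2).T, np.zeros(3)))


def z_rotation(deg: float) -> RigidTransform:
    a = np.radians(deg)
    R = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    return RigidTransform(R, np.zeros(3))
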