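import numpy as np
import pytest

import motifstruct as ms
from motifstruct.sslib import DEFAULT_RECIPES

SEED = 20121207


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def random_segment(rng, n_atoms):
    """A random coordinate cloud wrapped as a segment-like array."""
    return rng.normal(0.0, 3.0, (n_atoms, 3))


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0.0, 10.0, 3)
    return R, t


@pytest.fixture
def ideal_helix():
    return ms.build_ideal_backbone(DEFAULT_RECIPES["alpha-helix"], 8)


@pytest.fixture
def three_residue_pdb():
    """Hand-written 3-residue fixture (N, CA, C, CB per residue except the
    Gly, which has no CB)."""
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00",
        "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00",
        "ATOM      4  CB  ALA A   1       1.980  -0.773  -1.210  1.00  0.00",
        "ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00",
        "ATOM      6  CA  GLY A   2       4.040   2.800   0.100  1.00  0.00",
        "ATOM      7  C   GLY A   2       5.500   2.700   0.200  1.00  0.00",
        "ATOM      8  N   TYR A   3       6.200   3.800   0.300  1.00  0.00",
        "ATOM      9  CA  TYR A   3       7.650   3.900   0.400  1.00  0.00",
        "ATOM     10  C   TYR A   3       8.300   5.250   0.500  1.00  0.00",
        "ATOM     11  CB  TYR A   3       8.150   3.100   1.600  1.00  0.00",
        "END",
    ]
    return "\n".join(lines) + "\n"
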