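import numpy as np
import pytest

from modekit import (FixtureSpec, SpringModel, build_hessian,
                     build_spring_network, diagonalize_full, make_structure)

ONE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 11.00           C
ATOM      3  C   ALA A   1      10.571   5.703  -4.128  1.00 12.00           C
ATOM      4  O   ALA A   1       9.686   6.504  -3.823  1.00 13.00           O
"""

BAD_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.63x   6.071  -5.147  1.00 11.00           C
"""

MIXED_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60 11.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.200  0.40 11.50           C
ATOM      4  C   ALA A   1      10.571   5.703  -4.128  1.00 12.00           C
ATOM      5  O   ALA A   1       9.686   6.504  -3.823  1.00 13.00           O
ATOM      6  H   ALA A   1      11.500   6.000  -7.000  1.00  5.00           H
ATOM      7  N   GLY A   2       9.980   4.521  -4.012  1.00 14.00           N
ATOM      8  CA  GLY A   2       8.950   4.021  -3.105  1.00 15.00           C
ATOM      9  C   GLY A   2       7.600   4.400  -3.700  1.00 16.00           C
ATOM     10  O   GLY A   2       7.200   5.200  -4.500  1.00 17.00           O
HETATM   11 ZN    ZN A 101       5.000   5.000  -5.000  1.00 20.00          ZN
END
"""


@pytest.fixture
def mixed_pdb(tmp_path):
    path = tmp_path / "mixed.pdb"
    path.write_text(MIXED_PDB)
    return path


@pytest.fixture(scope="session")
def blob20():
    return make_structure(FixtureSpec("random_blob", 20, seed=1))


@pytest.fixture(scope="session")
def blob20_modes(blob20):
    network = build_spring_network(blob20, SpringModel())
    return diagonalize_full(build_hessian(network, blob20))


@pytest.fixture(scope="session")
def blob30():
    return make_structure(FixtureSpec("random_blob", 30, seed=7))


@pytest.fixture(scope="session")
def blob30_hessian(blob30):
    return build_hessian(build_spring_network(blob30, SpringModel()), blob30)


def random_unit_modes(rng: np.random.Generator, n_atoms: int, n_modes: int):
    """Synthetic orthonormal ModeSet over 3N coordinates."""
    from modekit import ModeSet
    q, _ = np.linalg.qr(rng.standard_normal((3 * n_atoms, n_modes)))
    lam = np.sort(rng.uniform(0.5, 5.0, size=n_modes))
    return ModeSet(lam, q, kind="nma")
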