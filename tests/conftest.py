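import numpy as np
import pytest
from hypothesis import settings

from crowdmd import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   2       0.000   2.000   0.000  1.00  0.00           O
END
"""

TOY_PQR = """\
ATOM      1  N   ALA A    1     0.0000     0.0000     0.0000   0.5000  1.5000
ATOM      2  CA  ALA A    1     1.5000     0.0000     0.0000  -0.5000  1.7000
ATOM      3  O   ALA A    2     0.0000     2.0000     0.0000   0.0000  1.4000
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1      20.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY B   2      23.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_pqr(tmp_path):
    p = tmp_path / "toy.pqr"
    p.write_text(TOY_PQR)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture(scope="session")
def template():
    """Full-size pseudo-protein template (70 residues, 250 D dipole)."""
    return synthetic.make_template()


@pytest.fixture(scope="session")
def small_template():
    """Small template for fast trajectory tests."""
    return synthetic.make_template(n_residues=12, dipole_target=30.0)


def brute_force_contact_count(
    coords_a, coords_b, cutoff=4.0, box_edge=None
) -> int:
    """Independent all-pairs oracle for the atom-counting contact convention."""
    a = np.asarray(coords_a)[:, None, :]
    b = np.asarray(coords_b)[None, :, :]
    d = a - b
    if box_edge is not None:
        d = d - box_edge * np.round(d / box_edge)
    dist = np.sqrt((d**2).sum(axis=-1))
    close = dist <= cutoff
    return int(close.any(axis=1).sum() + close.any(axis=0).sum())
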