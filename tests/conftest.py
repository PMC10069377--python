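import numpy as np
import pytest

from pdc.fixtures import FixtureSpec, generate_structure

GLY_PDB = """\
TITLE     MINIMAL GLYCINE TEST MODEL
COMPND    MOLECULE: TEST PEPTIDE; CHAIN: A
SOURCE    ORGANISM_SCIENTIFIC: SYNTHETIC CONSTRUCT; ORGANISM_TAXID: 32630
DBREF  XXXX A    1     1  UNP    P00000   TEST_SYNTH      1     1
ATOM      1  N   GLY A   1      -0.525   1.362   0.000  1.00 91.20           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00 91.20           C
ATOM      3  C   GLY A   1       1.526   0.000   0.000  1.00 91.20           C
ATOM      4  O   GLY A   1       2.153  -1.062   0.000  1.00 91.20           O
TER
END
"""


@pytest.fixture(scope="session")
def structure20():
    """Small mixed-conformation full-atomic structure, per-residue B-factors."""
    return generate_structure(FixtureSpec(n_res=20, seed=19, bfactor_mode=1))


@pytest.fixture(scope="session")
def structure50_mode2():
    return generate_structure(FixtureSpec(n_res=50, seed=7, bfactor_mode=2))


@pytest.fixture
def gly_pdb_path(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLY_PDB)
    return p


def assert_structures_equal(a, b, coord_tol=0.0, b_tol=0.0):
    __tracebackhide__ = True
    assert a.sequence == b.sequence
    assert a.residue_indices() == b.residue_indices()
    assert [x.name for x in a.iter_atoms()] == [x.name for x in b.iter_atoms()]
    if coord_tol == 0.0:
        assert np.array_equal(a.coords(), b.coords())
    else:
        assert np.abs(a.coords() - b.coords()).max() <= coord_tol
    if b_tol == 0.0:
        assert np.array_equal(a.bfactors(), b.bfactors())
    else:
        assert np.abs(a.bfactors() - b.bfactors()).max() <= b_tol
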