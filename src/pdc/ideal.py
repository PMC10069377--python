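"""Ideal covalent geometry used for torsion-space model building.

Bond lengths and angles are Engh & Huber-style protein values (the standard
restraint set behind most model-building tools, including the
PeptideBuilder lineage).  Exact decimals matter less than self-consistency:
the synthetic-structure generator and the lossy-decoder reconstruction share
this single table, and the codec's fragment fit to the stored CA trace
absorbs small deviations from any particular restraint library.

Side-chain atoms are described by placement rules: each atom is positioned
by NeRF from three previously placed atoms, an ideal bond and angle, and a
torsion that is either a chi angle (with a fixed offset for branch atoms,
e.g. OD2 = chi2 + 180) or a constant (planar-ring closure).
"""

from __future__ import annotations

from typing import NamedTuple

# --- backbone ---------------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329   # peptide bond
BOND_C_O = 1.231   # carbonyl, also used for OXT
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.5   # also CA-C-OXT
ANGLE_C_CA_CB = 110.1

#: Improper dihedral N-C-CA-CB fixing the L-alpha-carbon chirality
#: (IUPAC sign; verified against an energy-minimised L-alanine conformer).
DIHEDRAL_N_C_CA_CB = -122.69


class PlacementRule(NamedTuple):
    """How to place one side-chain atom.

    ``frame`` names three already-placed atoms (a, b, c); the new atom d
    satisfies |d-c| = ``bond``, angle(b,c,d) = ``angle`` and
    dihedral(a,b,c,d) = chi_k + ``offset`` when ``chi`` is k >= 1, or
    ``offset`` alone when ``chi`` is 0 (rigid ring closure).
    """

    atom: str
    frame: tuple[str, str, str]
    bond: float
    angle: float
    chi: int
    offset: float


def _r(atom, frame, bond, angle, chi, offset=0.0):
    return PlacementRule(atom, frame, bond, angle, chi, offset)


#: Placement rules per residue type, in dependency order (each frame atom is
#: either backbone or an earlier rule's atom).  CB is handled separately.
SIDECHAIN_RULES: dict[str, tuple[PlacementRule, ...]] = {
    "GLY": (),
    "ALA": (),
    "CYS": (_r("SG", ("N", "CA", "CB"), 1.808, 114.2, 1),),
    "SER": (_r("OG", ("N", "CA", "CB"), 1.417, 110.8, 1),),
    "THR": (
        _r("OG1", ("N", "CA", "CB"), 1.433, 109.6, 1),
        _r("CG2", ("N", "CA", "CB"), 1.521, 110.5, 1, -120.0),
    ),
    "VAL": (
        _r("CG1", ("N", "CA", "CB"), 1.527, 110.5, 1),
        _r("CG2", ("N", "CA", "CB"), 1.527, 110.5, 1, 122.0),
    ),
    "ILE": (
        _r("CG1", ("N", "CA", "CB"), 1.530, 110.4, 1),
        _r("CG2", ("N", "CA", "CB"), 1.521, 110.5, 1, -122.0),
        _r("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 2),
    ),
    "LEU": (
        _r("CG", ("N", "CA", "CB"), 1.530, 116.3, 1),
        _r("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 2),
        _r("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 2, 122.0),
    ),
    "ASP": (
        _r("CG", ("N", "CA", "CB"), 1.516, 112.6, 1),
        _r("OD1", ("CA", "CB", "CG"), 1.249, 118.5, 2),
        _r("OD2", ("CA", "CB", "CG"), 1.249, 118.5, 2, 180.0),
    ),
    "ASN": (
        _r("CG", ("N", "CA", "CB"), 1.516, 112.6, 1),
        _r("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 2),
        _r("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 2, 180.0),
    ),
    "GLU": (
        _r("CG", ("N", "CA", "CB"), 1.520, 114.1, 1),
        _r("CD", ("CA", "CB", "CG"), 1.516, 112.6, 2),
        _r("OE1", ("CB", "CG", "CD"), 1.249, 118.5, 3),
        _r("OE2", ("CB", "CG", "CD"), 1.249, 118.5, 3, 180.0),
    ),
    "GLN": (
        _r("CG", ("N", "CA", "CB"), 1.520, 114.1, 1),
        _r("CD", ("CA", "CB", "CG"), 1.516, 112.6, 2),
        _r("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 3),
        _r("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 3, 180.0),
    ),
    "MET": (
        _r("CG", ("N", "CA", "CB"), 1.520, 114.1, 1),
        _r("SD", ("CA", "CB", "CG"), 1.807, 112.7, 2),
        _r("CE", ("CB", "CG", "SD"), 1.789, 100.8, 3),
    ),
    "LYS": (
        _r("CG", ("N", "CA", "CB"), 1.520, 114.1, 1),
        _r("CD", ("CA", "CB", "CG"), 1.520, 111.3, 2),
        _r("CE", ("CB", "CG", "CD"), 1.520, 111.3, 3),
        _r("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 4),
    ),
    "ARG": (
        _r("CG", ("N", "CA", "CB"), 1.520, 114.1, 1),
        _r("CD", ("CA", "CB", "CG"), 1.520, 111.3, 2),
        _r("NE", ("CB", "CG", "CD"), 1.461, 111.5, 3),
        _r("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 4),
        _r("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 5),
        _r("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 5, 180.0),
    ),
    # PRO: CG/CD from chi1/chi2 with ring-like ideal values; no closure
    # minimisation (CD-N distance is near-ideal for rotamer-like chi).
    "PRO": (
        _r("CG", ("N", "CA", "CB"), 1.495, 104.5, 1),
        _r("CD", ("CA", "CB", "CG"), 1.507, 106.1, 2),
    ),
    "HIS": (
        _r("CG", ("N", "CA", "CB"), 1.497, 113.8, 1),
        _r("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 2),
        _r("CD2", ("CA", "CB", "CG"), 1.354, 129.1, 2, 180.0),
        _r("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 0, 180.0),
        _r("NE2", ("CG", "ND1", "CE1"), 1.321, 108.4, 0, 0.0),
    ),
    "PHE": (
        _r("CG", ("N", "CA", "CB"), 1.502, 113.8, 1),
        _r("CD1", ("CA", "CB", "CG"), 1.391, 120.8, 2),
        _r("CD2", ("CA", "CB", "CG"), 1.391, 120.8, 2, 180.0),
        _r("CE1", ("CB", "CG", "CD1"), 1.391, 120.8, 0, 180.0),
        _r("CE2", ("CB", "CG", "CD2"), 1.391, 120.8, 0, 180.0),
        _r("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0, 0.0),
    ),
    "TYR": (
        _r("CG", ("N", "CA", "CB"), 1.502, 113.8, 1),
        _r("CD1", ("CA", "CB", "CG"), 1.391, 120.8, 2),
        _r("CD2", ("CA", "CB", "CG"), 1.391, 120.8, 2, 180.0),
        _r("CE1", ("CB", "CG", "CD1"), 1.391, 120.8, 0, 180.0),
        _r("CE2", ("CB", "CG", "CD2"), 1.391, 120.8, 0, 180.0),
        _r("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0, 0.0),
        _r("OH", ("CD1", "CE1", "CZ"), 1.377, 119.9, 0, 180.0),
    ),
    "TRP": (
        _r("CG", ("N", "CA", "CB"), 1.498, 113.6, 1),
        _r("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 2),
        _r("CD2", ("CA", "CB", "CG"), 1.433, 126.7, 2, 180.0),
        _r("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 0, 180.0),
        _r("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 0, 180.0),
        _r("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0, 0.0),
        _r("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 0, 180.0),
        _r("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 0, 180.0),
        _r("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0, 0.0),
    ),
}

#: Bonded atom pairs per residue type (side chain + attachment to CA),
#: used by chemical-sanity checks.  Backbone N-CA, CA-C, C-O, C-N(+1) are
#: implicit.
def bonded_pairs(res_type: str) -> list[tuple[str, str, float]]:
    """(atom1, atom2, ideal bond length) for every side-chain bond."""
    pairs: list[tuple[str, str, float]] = []
    if res_type != "GLY":
        pairs.append(("CA", "CB", BOND_CA_CB))
    for rule in SIDECHAIN_RULES[res_type]:
        pairs.append((rule.frame[2], rule.atom, rule.bond))
    return pairs
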