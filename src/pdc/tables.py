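"""Canonical per-residue atom ordering and side-chain torsion definitions.

Atoms within a residue are stored in a fixed order chosen so that each atom
is spatially close to its predecessor (backbone first, then side chain
walking outward).  Short inter-atom distances are what make the 2-byte delta
encoding of the lossless codec work, so every codec stage depends on this
table.  The order is *not* derivable from topology (e.g. HIS lists
``CG CD2 ND1 CE1 NE2``); it is transcribed literally.

Side-chain torsion (chi) angles follow the Dunbrack rotamer-library atom
quadruples.  GLY and ALA have none; ARG has five.
"""

from __future__ import annotations

from .errors import UnsupportedResidueError

#: Canonical heavy-atom order per residue type (OXT excluded; it is appended
#: to the final residue of a chain).
ATOM_ORDER: dict[str, tuple[str, ...]] = {
    "GLY": ("N", "CA", "C", "O"),
    "ALA": ("N", "CA", "C", "CB", "O"),
    "CYS": ("N", "CA", "C", "CB", "O", "SG"),
    "ASP": ("N", "CA", "C", "CB", "O", "CG", "OD1", "OD2"),
    "GLU": ("N", "CA", "C", "CB", "O", "CG", "CD", "OE1", "OE2"),
    "PHE": ("N", "CA", "C", "CB", "O", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("N", "CA", "C", "CB", "O", "CG", "CD2", "ND1", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "CB", "O", "CG1", "CG2", "CD1"),
    "LYS": ("N", "CA", "C", "CB", "O", "CG", "CD", "CE", "NZ"),
    "LEU": ("N", "CA", "C", "CB", "O", "CG", "CD1", "CD2"),
    "MET": ("N", "CA", "C", "CB", "O", "CG", "SD", "CE"),
    "ASN": ("N", "CA", "C", "CB", "O", "CG", "ND2", "OD1"),
    "PRO": ("N", "CA", "C", "CB", "O", "CG", "CD"),
    "GLN": ("N", "CA", "C", "CB", "O", "CG", "CD", "NE2", "OE1"),
    "ARG": ("N", "CA", "C", "CB", "O", "CG", "CD", "NE", "NH1", "NH2", "CZ"),
    "SER": ("N", "CA", "C", "CB", "O", "OG"),
    "THR": ("N", "CA", "C", "CB", "O", "CG2", "OG1"),
    "VAL": ("N", "CA", "C", "CB", "O", "CG1", "CG2"),
    "TRP": ("N", "CA", "C", "CB", "O", "CG", "CD1", "CD2", "CE2", "CE3",
            "NE1", "CH2", "CZ2", "CZ3"),
    "TYR": ("N", "CA", "C", "CB", "O", "CG", "CD1", "CD2", "CE1", "CE2",
            "OH", "CZ"),
}

#: Dunbrack chi-angle atom quadruples.  chi_k of a residue is the dihedral
#: over the k-th quadruple.  The last atom of quadruple k is the atom whose
#: position chi_k determines.
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "GLY": (),
    "ALA": (),
    "CYS": (("N", "CA", "CB", "SG"),),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "VAL": (("N", "CA", "CB", "CG1"),),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")),
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")),
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_RESIDUES = frozenset(ATOM_ORDER)


def _check_res_type(res_type: str) -> None:
    if res_type not in ATOM_ORDER:
        raise UnsupportedResidueError(f"unsupported residue type {res_type!r}")


def canonical_atom_order(res_type: str, is_last_residue: bool = False) -> list[str]:
    """Return the canonical atom-name order for ``res_type``.

    When ``is_last_residue`` is true the terminal carboxylate oxygen ``OXT``
    is appended as the final name.
    """
    _check_res_type(res_type)
    names = list(ATOM_ORDER[res_type])
    if is_last_residue:
        names.append("OXT")
    return names


def sidechain_torsion_count(res_type: str) -> int:
    """Number of side-chain chi angles defined for ``res_type`` (0-5)."""
    _check_res_type(res_type)
    return len(CHI_ATOMS[res_type])
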