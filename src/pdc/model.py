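"""In-memory model of a single-chain protein structure.

The model is deliberately minimal: one chain, standard amino acids only,
no heteroatoms, no altlocs, no hydrogens — the dialect of predicted models
(AlphaFold-style), which is the only input the codec accepts.  Coordinates
live as float64 angstroms but are only meaningful at 3 decimals (the fixed
precision of PDB/mmCIF text); temperature factors at 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (IncompleteResidueError, UnsupportedResidueError,
                     ValidationError)
from .tables import ATOM_ORDER, THREE_TO_ONE, canonical_atom_order

#: Printable PDB coordinate range (fixed 8.3 column).
COORD_MIN, COORD_MAX = -999.0, 9999.0
#: Temperature-factor range imposed by 2-byte storage at 0.01 granularity.
BFACTOR_MIN, BFACTOR_MAX = -327.68, 327.67


@dataclass
class Atom:
    """A heavy atom: name, Cartesian coordinate (Å) and temperature factor.

    In predicted models the temperature-factor column carries the pLDDT
    confidence (0-100), constant within a residue.
    """

    name: str
    coord: np.ndarray  # shape (3,), Å
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValidationError(f"atom {self.name}: coord must be a 3-vector")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (self.name == other.name
                and np.array_equal(self.coord, other.coord)
                and self.bfactor == other.bfactor)


@dataclass
class Residue:
    """One amino-acid residue: 3-letter type, author index, ordered atoms."""

    res_type: str
    res_index: int
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.res_type}{self.res_index} has no atom {name!r}")

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Residue):
            return NotImplemented
        return (self.res_type == other.res_type
                and self.res_index == other.res_index
                and self.atoms == other.atoms)


@dataclass
class HeaderMeta:
    """Free-text header fields preserved by the container.

    ``title``: model title; ``compound``: molecule name and chain id;
    ``source``: organism and NCBI taxon; ``dbref``: UniProt accession /
    entry / mapped range.  Any field may be empty; all are round-tripped
    verbatim through the binary container.
    """

    title: str = ""
    compound: str = ""
    source: str = ""
    dbref: str = ""


@dataclass
class Structure:
    """A single protein chain plus its header metadata.

    ``ca_only`` marks reduced structures holding exactly one CA atom per
    residue.  Residue indices must be strictly increasing.
    """

    chain_id: str = "A"
    residues: list[Residue] = field(default_factory=list)
    header: HeaderMeta = field(default_factory=HeaderMeta)
    ca_only: bool = False

    # -- derived views -------------------------------------------------

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.res_type] for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue_indices(self) -> list[int]:
        return [r.res_index for r in self.residues]

    def iter_atoms(self):
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) float array, chain order."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.stack([a.coord for a in self.iter_atoms()])

    def bfactors(self) -> np.ndarray:
        return np.array([a.bfactor for a in self.iter_atoms()])

    def ca_coords(self) -> np.ndarray:
        """CA coordinates, one row per residue."""
        return np.stack([r.atom("CA").coord for r in self.residues])

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValidationError`` /
        ``IncompleteResidueError`` on the first violation."""
        if not self.residues:
            raise ValidationError("structure has no residues")
        idx = self.residue_indices()
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("residue indices are not strictly increasing")
        last = len(self.residues) - 1
        for i, res in enumerate(self.residues):
            if res.res_type not in ATOM_ORDER:
                raise UnsupportedResidueError(
                    f"residue {res.res_index}: unsupported type {res.res_type!r}")
            names = res.atom_names()
            if self.ca_only:
                if names != ["CA"]:
                    raise IncompleteResidueError(
                        f"residue {res.res_index}: CA-only structure must hold "
                        f"exactly one CA atom, got {names}")
                continue
            want = canonical_atom_order(
                res.res_type,
                is_last_residue=(i == last and "OXT" in names))
            if names != want:
                _diff_atoms(res, names, want)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return (self.chain_id == other.chain_id
                and self.ca_only == other.ca_only
                and self.header == other.header
                and self.residues == other.residues)


def _diff_atoms(res: Residue, names: list[str], want: list[str]) -> None:
    missing = [n for n in want if n not in names]
    extra = [n for n in names if n not in want]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing {missing}")
        if extra:
            parts.append(f"unexpected {extra}")
        raise IncompleteResidueError(
            f"residue {res.res_type}{res.res_index}: " + ", ".join(parts))
    raise IncompleteResidueError(
        f"residue {res.res_type}{res.res_index}: atoms out of canonical order "
        f"{names} (expected {want})")


def to_ca_only(structure: Structure) -> Structure:
    """Reduce to the CA-trace representation (one CA atom per residue)."""
    if structure.ca_only:
        return structure
    residues = [replace(r, atoms=[r.atom("CA")]) for r in structure.residues]
    return replace(structure, residues=residues, ca_only=True)


def reorder_to_canonical(structure: Structure) -> Structure:
    """Return a copy with each residue's atoms permuted to canonical order.

    Every residue must contain exactly the atoms its type defines (in any
    order); coordinates and B-factors are untouched.  Idempotent.
    """
    last = len(structure.residues) - 1
    new_residues = []
    for i, res in enumerate(structure.residues):
        if structure.ca_only:
            want = ["CA"]
        else:
            has_oxt = any(a.name == "OXT" for a in res.atoms)
            want = canonical_atom_order(
                res.res_type, is_last_residue=(i == last and has_oxt))
        by_name = {a.name: a for a in res.atoms}
        if len(by_name) != len(res.atoms):
            raise IncompleteResidueError(
                f"residue {res.res_type}{res.res_index}: duplicate atom names")
        if sorted(by_name) != sorted(want):
            _diff_atoms(res, res.atom_names(), want)
        new_residues.append(replace(res, atoms=[by_name[n] for n in want]))
    out = replace(structure, residues=new_residues)
    return out
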