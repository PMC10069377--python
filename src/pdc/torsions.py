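"""Backbone and side-chain torsion extraction.

Conventions:

* ``phi_i``   = C(i-1) - N(i) - CA(i) - C(i)         (undefined for i = 1)
* ``psi_i``   = N(i) - CA(i) - C(i) - N(i+1)         (undefined for i = n)
* ``omega_i`` = CA(i-1) - C(i-1) - N(i) - CA(i)      (undefined for i = 1);
  omega is indexed by the residue it *precedes*, i.e. omega_i belongs to
  the peptide bond entering residue i.
* chi angles follow the Dunbrack quadruples in :mod:`pdc.tables`.

Undefined torsions are ``None``; they occur only at chain termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .geometry import dihedral
from .model import Structure
from .tables import CHI_ATOMS


@dataclass
class TorsionRecord:
    """Per-residue torsions in degrees, range (-180, 180]."""

    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    chis: list[float] = field(default_factory=list)


def extract_torsions(structure: Structure) -> list[TorsionRecord]:
    """Measure all backbone and side-chain torsions of a full-atomic
    structure (one record per residue)."""
    if structure.ca_only:
        raise ValidationError("torsion extraction requires a full-atomic structure")
    res = structure.residues
    records = []
    for i, r in enumerate(res):
        n, ca, c = (r.atom(x).coord for x in ("N", "CA", "C"))
        rec = TorsionRecord()
        if i > 0:
            prev_c = res[i - 1].atom("C").coord
            prev_ca = res[i - 1].atom("CA").coord
            rec.phi = dihedral(prev_c, n, ca, c)
            rec.omega = dihedral(prev_ca, prev_c, n, ca)
        if i < len(res) - 1:
            next_n = res[i + 1].atom("N").coord
            rec.psi = dihedral(n, ca, c, next_n)
        for quad in CHI_ATOMS[r.res_type]:
            rec.chis.append(dihedral(*(r.atom(name).coord for name in quad)))
        records.append(rec)
    return records
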