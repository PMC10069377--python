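"""Full-atomic reconstruction from sequence, torsions and a CA trace.

Decoding a lossy payload recovers (a) the quantized CA trace in Cartesian
space and (b) the quantized torsions.  Reconstruction combines both: a
full-atomic model is first built in torsion space with ideal bonds and
angles (PeptideBuilder-style NeRF chain extension), then three-residue
fragments of that model are least-squares-fitted onto the CA trace,
anchoring the globally drift-prone torsion model to the globally faithful
Cartesian trace.  Each residue takes the transform of the fragment centred
on it (terminal residues use the first/last full window), so fragments
overlap and no tiling seams arise.
"""

from __future__ import annotations

import numpy as np

from . import ideal
from .errors import ValidationError
from .geometry import _kabsch, place_atom
from .model import Atom, Residue, Structure
from .tables import ONE_TO_THREE, canonical_atom_order, sidechain_torsion_count
from .torsions import TorsionRecord

_TRANS = 180.0  # default for undefined phi/psi/omega at termini


def _residue_types(sequence: str) -> list[str]:
    try:
        return [ONE_TO_THREE[c] for c in sequence]
    except KeyError as exc:
        raise ValidationError(f"unknown one-letter code {exc.args[0]!r}") from exc


def build_torsion_space_model(
    sequence: str,
    torsions: list[TorsionRecord],
    *,
    add_oxt: bool = True,
    res_indices: list[int] | None = None,
) -> Structure:
    """Build a full-atomic chain with ideal geometry and the given torsions.

    The first residue is placed in a canonical frame: N at the origin, CA on
    +x, C in the xy-plane.  Undefined backbone torsions (``None``) take the
    trans value 180° for chain extension; an undefined psi places the
    carbonyl O at dihedral N-CA-C-O = 180°.
    """
    if len(torsions) != len(sequence):
        raise ValidationError(
            f"{len(sequence)} residues but {len(torsions)} torsion records")
    types = _residue_types(sequence)
    for t, rec in zip(types, torsions):
        want = sidechain_torsion_count(t)
        if len(rec.chis) != want:
            raise ValidationError(
                f"{t} requires {want} chi angles, got {len(rec.chis)}")
    if res_indices is None:
        res_indices = list(range(1, len(sequence) + 1))

    n = len(sequence)
    residues: list[Residue] = []
    prev: dict[str, np.ndarray] = {}
    for i, (res_type, rec) in enumerate(zip(types, torsions)):
        pos: dict[str, np.ndarray] = {}
        if i == 0:
            ang = np.radians(ideal.ANGLE_N_CA_C)
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([ideal.BOND_N_CA, 0.0, 0.0])
            pos["C"] = pos["CA"] + ideal.BOND_CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            psi_prev = torsions[i - 1].psi
            pos["N"] = place_atom(
                prev["N"], prev["CA"], prev["C"],
                ideal.BOND_C_N, ideal.ANGLE_CA_C_N,
                _TRANS if psi_prev is None else psi_prev)
            pos["CA"] = place_atom(
                prev["CA"], prev["C"], pos["N"],
                ideal.BOND_N_CA, ideal.ANGLE_C_N_CA,
                _TRANS if rec.omega is None else rec.omega)
            pos["C"] = place_atom(
                prev["C"], pos["N"], pos["CA"],
                ideal.BOND_CA_C, ideal.ANGLE_N_CA_C,
                _TRANS if rec.phi is None else rec.phi)
        # carbonyl O from psi (anti to the next N); OXT anti to O
        o_torsion = (rec.psi + _TRANS) if rec.psi is not None else _TRANS
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                              ideal.BOND_C_O, ideal.ANGLE_CA_C_O, o_torsion)
        if res_type != "GLY":
            pos["CB"] = place_atom(pos["N"], pos["C"], pos["CA"],
                                   ideal.BOND_CA_CB, ideal.ANGLE_C_CA_CB,
                                   ideal.DIHEDRAL_N_C_CA_CB)
        for rule in ideal.SIDECHAIN_RULES[res_type]:
            torsion = rule.offset if rule.chi == 0 else rec.chis[rule.chi - 1] + rule.offset
            a, b, c = (pos[name] for name in rule.frame)
            pos[rule.atom] = place_atom(a, b, c, rule.bond, rule.angle, torsion)
        is_last = i == n - 1
        if is_last and add_oxt:
            pos["OXT"] = place_atom(pos["N"], pos["CA"], pos["C"],
                                    ideal.BOND_C_O, ideal.ANGLE_CA_C_O,
                                    o_torsion + _TRANS)
        order = canonical_atom_order(res_type, is_last_residue=(is_last and add_oxt))
        residues.append(Residue(res_type, res_indices[i],
                                [Atom(name, pos[name]) for name in order]))
        prev = pos
    return Structure(residues=residues)


def fit_fragments_to_ca(torsion_model: Structure, ca_trace: np.ndarray) -> Structure:
    """Anchor a torsion-space model to a CA trace by overlapping
    three-residue least-squares fits.

    For residue i the window (i-1, i, i+1) — clamped to the first/last
    three residues at the termini — is superposed by its CA atoms onto the
    corresponding trace points, and the resulting rigid transform is
    applied to *all* atoms of residue i.  The output CA is the transform
    image of the model CA (not snapped to the trace), which keeps every
    residue's internal geometry exactly ideal.

    Chains of fewer than three residues fall back to a whole-chain fit
    (translation for a single residue).
    """
    ca_trace = np.asarray(ca_trace, dtype=float)
    n = torsion_model.n_residues
    if ca_trace.shape != (n, 3):
        raise ValidationError(
            f"CA trace has shape {ca_trace.shape}, expected ({n}, 3)")
    model_ca = torsion_model.ca_coords()
    out_residues = []
    for i, res in enumerate(torsion_model.residues):
        if n >= 3:
            lo = min(max(i - 1, 0), n - 3)
            window = slice(lo, lo + 3)
        else:
            window = slice(0, n)
        if n == 1:
            shift = ca_trace[0] - model_ca[0]
            moved = [Atom(a.name, a.coord + shift, a.bfactor) for a in res.atoms]
        elif n == 2:
            transform = _two_point_fit(ca_trace, model_ca)
            moved = [Atom(a.name, transform.apply(a.coord), a.bfactor)
                     for a in res.atoms]
        else:
            transform, _ = _kabsch(ca_trace[window], model_ca[window])
            moved = [Atom(a.name, transform.apply(a.coord), a.bfactor)
                     for a in res.atoms]
        out_residues.append(Residue(res.res_type, res.res_index, moved))
    return Structure(chain_id=torsion_model.chain_id, residues=out_residues,
                     header=torsion_model.header, ca_only=False)


def _two_point_fit(ca_trace: np.ndarray, model_ca: np.ndarray):
    """Two CA pairs leave the rotation about the CA-CA axis undefined;
    take the *minimal* rotation aligning the model CA vector to the trace
    vector, plus the centroid translation."""
    from scipy.spatial.transform import Rotation

    from .geometry import RigidTransform

    v_mov = model_ca[1] - model_ca[0]
    v_ref = ca_trace[1] - ca_trace[0]
    rot, _ = Rotation.align_vectors(v_ref[None, :], v_mov[None, :])
    r = rot.as_matrix()
    t = ca_trace.mean(axis=0) - r @ model_ca.mean(axis=0)
    return RigidTransform(r, t)


def rebuild(
    sequence: str,
    torsions: list[TorsionRecord],
    ca_trace: np.ndarray,
    bfactors: np.ndarray | None = None,
    *,
    add_oxt: bool = True,
    res_indices: list[int] | None = None,
    round_decimals: int | None = 3,
) -> Structure:
    """Full lossy-decode reconstruction: torsion-space build, fragment fit
    to the CA trace, per-residue B-factor attachment.

    ``bfactors`` may be one value per residue (applied to all its atoms) or
    one per atom in canonical order.  Coordinates are rounded to file
    precision (3 decimals) unless ``round_decimals`` is ``None``.
    """
    model = build_torsion_space_model(sequence, torsions, add_oxt=add_oxt,
                                      res_indices=res_indices)
    fitted = fit_fragments_to_ca(model, ca_trace)
    if bfactors is not None:
        _attach_bfactors(fitted, np.asarray(bfactors, dtype=float))
    if round_decimals is not None:
        for atom in fitted.iter_atoms():
            atom.coord = np.round(atom.coord, round_decimals)
    return fitted


def _attach_bfactors(structure: Structure, bfactors: np.ndarray) -> None:
    if bfactors.shape == (structure.n_residues,):
        for res, b in zip(structure.residues, bfactors):
            for atom in res.atoms:
                atom.bfactor = float(b)
    elif bfactors.shape == (structure.n_atoms,):
        for atom, b in zip(structure.iter_atoms(), bfactors):
            atom.bfactor = float(b)
    else:
        raise ValidationError(
            f"bfactors shape {bfactors.shape} matches neither residue count "
            f"({structure.n_residues}) nor atom count ({structure.n_atoms})")
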