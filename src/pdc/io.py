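"""Reading and writing AlphaFold-dialect mmCIF and PDB files.

Only the subset those files actually use is supported: single protein
chain, ATOM records, no altlocs, no insertion codes, no heteroatoms.
Hydrogens are stripped on read (models from pipelines that keep them are
benchmarked heavy-atom-only).  gemmi does the mmCIF/PDB coordinate
parsing; PDB header records (TITLE/COMPND/SOURCE/DBREF) are captured from
the raw lines so they round-trip verbatim, since gemmi decomposes them
into structured objects.

Header mapping for mmCIF (read and write):

========  =========================================
title     ``_struct.title``
compound  ``_entity.pdbx_description``
source    ``_entity_src_nat.pdbx_organism_scientific``
dbref     ``_struct_ref.pdbx_db_accession``
========  =========================================
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import FormatError, RangeError, UnsupportedInputError
from .model import (COORD_MAX, COORD_MIN, Atom, HeaderMeta, Residue,
                    Structure, reorder_to_canonical)
from .tables import STANDARD_RESIDUES

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class FormatKind:
    """Detected on-disk representation."""

    kind: str  # "pdb" | "mmcif" | "pdc"
    gzipped: bool = False


def detect_format(path: str | Path) -> FormatKind:
    """Detect the file format from magic bytes, falling back to the
    extension for empty/ambiguous files."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(2)
        gzipped = head == _GZIP_MAGIC
    if gzipped:
        with gzip.open(path, "rb") as fh:
            head = fh.read(4096)
    else:
        with open(path, "rb") as fh:
            head = fh.read(4096)
    if head.startswith(b"PDC"):
        return FormatKind("pdc", gzipped=False)  # PDC is gzip-wrapped itself
    suffixes = [s.lower() for s in path.suffixes]
    if ".pdc" in suffixes:
        return FormatKind("pdc", gzipped=False)
    text = head.decode("utf-8", errors="replace")
    if text.lstrip().startswith("data_") or "_atom_site" in text:
        return FormatKind("mmcif", gzipped=gzipped)
    if any(text.lstrip().startswith(rec) for rec in
           ("HEADER", "TITLE", "COMPND", "SOURCE", "DBREF", "SEQRES",
            "ATOM", "MODEL", "REMARK")):
        return FormatKind("pdb", gzipped=gzipped)
    if ".cif" in suffixes:
        return FormatKind("mmcif", gzipped=gzipped)
    if ".pdb" in suffixes or ".ent" in suffixes:
        return FormatKind("pdb", gzipped=gzipped)
    raise FormatError(f"cannot detect format of {path}")


def _read_text(path: Path, gzipped: bool) -> str:
    opener = gzip.open if gzipped else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return fh.read()


def read_structure(path: str | Path, format: FormatKind | None = None) -> Structure:
    """Read a single-chain structure from PDB, mmCIF or PDC (plain or
    GZIP), returning it in canonical atom order."""
    path = Path(path)
    fmt = format or detect_format(path)
    if fmt.kind == "pdc":
        from .lossy import decompress
        return decompress(path.read_bytes())
    text = _read_text(path, fmt.gzipped)
    try:
        if fmt.kind == "pdb":
            header = _scan_pdb_header(text)
            st = gemmi.read_pdb_string(text)
        elif fmt.kind == "mmcif":
            doc = gemmi.cif.read_string(text)
            block = doc.sole_block()
            header = _read_cif_header(block)
            st = gemmi.make_structure_from_block(block)
        else:
            raise FormatError(f"unknown format kind {fmt.kind!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    return _from_gemmi(st, header)


def _scan_pdb_header(text: str) -> HeaderMeta:
    fields = {"TITLE": [], "COMPND": [], "SOURCE": [], "DBREF": []}
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec in ("TITLE", "COMPND", "SOURCE"):
            fields[rec].append(line[10:].rstrip())
        elif rec == "DBREF":
            fields[rec].append(line[7:].rstrip())
    return HeaderMeta(
        title=" ".join(s.strip() for s in fields["TITLE"]).strip(),
        compound=" ".join(s.strip() for s in fields["COMPND"]).strip(),
        source=" ".join(s.strip() for s in fields["SOURCE"]).strip(),
        dbref=" ".join(s.strip() for s in fields["DBREF"]).strip(),
    )


def _cif_value(block, tag: str) -> str:
    val = block.find_value(tag)
    if val is None or val in (".", "?"):
        return ""
    return gemmi.cif.as_string(val)


def _read_cif_header(block) -> HeaderMeta:
    return HeaderMeta(
        title=_cif_value(block, "_struct.title"),
        compound=_cif_value(block, "_entity.pdbx_description"),
        source=_cif_value(block, "_entity_src_nat.pdbx_organism_scientific"),
        dbref=_cif_value(block, "_struct_ref.pdbx_db_accession"),
    )


def _from_gemmi(st: gemmi.Structure, header: HeaderMeta) -> Structure:
    if len(st) == 0:
        raise FormatError("file contains no model")
    if len(st) > 1:
        raise UnsupportedInputError("multi-model files are not supported")
    model = st[0]
    if len(model) != 1:
        raise UnsupportedInputError(
            f"expected a single chain, found {len(model)}")
    chain = model[0]
    residues: list[Residue] = []
    for res in chain:
        if res.het_flag == "H":
            raise UnsupportedInputError(
                f"HETATM record for residue {res.name} {res.seqid.num}")
        if res.name not in STANDARD_RESIDUES:
            raise UnsupportedInputError(
                f"non-standard residue {res.name} {res.seqid.num}")
        if res.seqid.icode not in (" ", "", "\x00"):
            raise UnsupportedInputError(
                f"insertion code at residue {res.seqid.num}{res.seqid.icode}")
        atoms = []
        for atom in res:
            if atom.altloc not in ("", "\x00", " ", "A"):
                raise UnsupportedInputError(
                    f"alternate location {atom.altloc!r} at residue "
                    f"{res.seqid.num}")
            if atom.altloc == "A":
                raise UnsupportedInputError(
                    f"alternate locations at residue {res.seqid.num}")
            if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                continue  # hydrogens are outside the format's scope
            coord = np.round([atom.pos.x, atom.pos.y, atom.pos.z], 3)
            atoms.append(Atom(atom.name, coord, round(float(atom.b_iso), 2)))
        residues.append(Residue(res.name, res.seqid.num, atoms))
    ca_only = all(r.atom_names() == ["CA"] for r in residues)
    structure = Structure(chain_id=chain.name or "A", residues=residues,
                          header=header, ca_only=ca_only)
    structure = reorder_to_canonical(structure)
    structure.validate()
    return structure


# --- writing ----------------------------------------------------------


def write_structure(structure: Structure, path: str | Path,
                    format: FormatKind | None = None) -> None:
    """Write a structure as PDB or mmCIF (GZIP if the path ends in .gz)."""
    path = Path(path)
    if format is None:
        suffixes = [s.lower() for s in path.suffixes]
        gzipped = suffixes[-1:] == [".gz"]
        core = suffixes[-2] if gzipped and len(suffixes) > 1 else (
            suffixes[-1] if suffixes else "")
        if core == ".cif":
            format = FormatKind("mmcif", gzipped)
        elif core in (".pdb", ".ent"):
            format = FormatKind("pdb", gzipped)
        else:
            raise FormatError(f"cannot infer output format from {path.name}")
    coords = structure.coords()
    if coords.size and (coords.min() < COORD_MIN or coords.max() > COORD_MAX):
        raise RangeError(
            "coordinates exceed the fixed-width text range "
            f"{COORD_MIN}..{COORD_MAX} Å")
    text = (to_pdb_string(structure) if format.kind == "pdb"
            else to_mmcif_string(structure))
    if format.gzipped:
        with open(path, "wb") as fh:
            fh.write(gzip.compress(text.encode(), compresslevel=9, mtime=0))
    else:
        path.write_text(text)


def _pdb_atom_name(name: str) -> str:
    # single-letter elements: short names are centred starting at column 14
    return f" {name:<3s}" if len(name) < 4 else name


def to_pdb_string(structure: Structure) -> str:
    """Fixed-column PDB text: header records, SEQRES, ATOM/TER/END."""
    h = structure.header
    lines = []
    if h.title:
        lines.append(f"TITLE     {h.title}")
    if h.compound:
        lines.append(f"COMPND    {h.compound}")
    if h.source:
        lines.append(f"SOURCE    {h.source}")
    if h.dbref:
        lines.append(f"DBREF  {h.dbref}")
    res_names = [r.res_type for r in structure.residues]
    for i in range(0, len(res_names), 13):
        lines.append(f"SEQRES {i // 13 + 1:3d} {structure.chain_id:1s} "
                     f"{len(res_names):4d}  " + " ".join(res_names[i:i + 13]))
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {_pdb_atom_name(atom.name):<4s} "
                f"{res.res_type:3s} {structure.chain_id:1s}{res.res_index:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.name[0]:>2s}")
    lines.append(f"TER   {serial + 1:5d}      "
                 f"{structure.residues[-1].res_type:3s} "
                 f"{structure.chain_id:1s}{structure.residues[-1].res_index:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def to_mmcif_string(structure: Structure) -> str:
    """Minimal PDBx/mmCIF text with the categories the dialect needs."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("model")
    h = structure.header
    if h.title:
        block.set_pair("_struct.title", gemmi.cif.quote(h.title))
    if h.compound:
        block.set_pair("_entity.pdbx_description", gemmi.cif.quote(h.compound))
    if h.source:
        block.set_pair("_entity_src_nat.pdbx_organism_scientific",
                       gemmi.cif.quote(h.source))
    if h.dbref:
        block.set_pair("_struct_ref.pdbx_db_accession", gemmi.cif.quote(h.dbref))
    loop = block.init_loop("_atom_site.", [
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
        "auth_seq_id", "auth_asym_id", "Cartn_x", "Cartn_y", "Cartn_z",
        "occupancy", "B_iso_or_equiv", "pdbx_PDB_model_num",
    ])
    serial = 0
    for label_seq, res in enumerate(structure.residues, start=1):
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coord
            loop.add_row([
                "ATOM", str(serial), atom.name[0], atom.name, ".",
                res.res_type, structure.chain_id, "1", str(label_seq),
                str(res.res_index), structure.chain_id,
                f"{x:.3f}", f"{y:.3f}", f"{z:.3f}",
                "1.00", f"{atom.bfactor:.2f}", "1",
            ])
    return doc.as_string()
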