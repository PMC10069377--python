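"""Lossless codec: integer encoding, delta encoding, binary packing.

Coordinates are exact at 0.001 Å and temperature factors at 0.01 — the
native precision of PDB/mmCIF text — so the round trip is bit-exact at
file precision.  Scaled to integers (x1000 / x100), coordinates fit 4-byte
integers; because sequentially adjacent atoms are covalently close, the
*differences* between an atom and its reference atom fit 2-byte integers.
The delta reference is the previous atom in canonical order within the
residue; each residue's first atom (N) references the previous residue's
carboxyl C (they are ~1.3 Å apart across the peptide bond).  CA-only
structures chain CA to CA.

The packed record (magic, flags, header strings, sequence, residue-index
ranges, then the numeric blocks) is GZIP-wrapped.  See FORMAT.md for the
byte-level layout.
"""

from __future__ import annotations

import gzip
import math
import struct

import numpy as np

from .errors import (CorruptionError, DeltaOverflowError, FormatError,
                     RangeError, ValidationError)
from .model import (BFACTOR_MAX, BFACTOR_MIN, COORD_MAX, COORD_MIN, Atom,
                    HeaderMeta, Residue, Structure)
from .tables import ONE_TO_THREE, canonical_atom_order

MAGIC = b"PDC"
VERSION = 1
FLAG_LOSSY = 0x01
FLAG_CA_ONLY = 0x02
FLAG_HAS_OXT = 0x04

GZIP_LEVEL = 9  # fixed for reproducible byte output

# --- scalar integer encoding -----------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def encode_coord_int(x: float) -> int:
    """Scale a coordinate (Å, 3 decimals) to a 4-byte integer (0.001 Å)."""
    if not (COORD_MIN <= x <= COORD_MAX):
        raise RangeError(
            f"coordinate {x} outside the representable range "
            f"{COORD_MIN}..{COORD_MAX} Å")
    return _round_half_away(x * 1000.0)


def decode_coord_int(i: int) -> float:
    return i / 1000.0


def encode_bfactor_int(b: float) -> int:
    """Scale a temperature factor (2 decimals) to a 2-byte integer (0.01)."""
    if not (BFACTOR_MIN <= b <= BFACTOR_MAX):
        raise RangeError(
            f"temperature factor {b} outside the representable range "
            f"{BFACTOR_MIN}..{BFACTOR_MAX}")
    return _round_half_away(b * 100.0)


def decode_bfactor_int(i: int) -> float:
    return i / 100.0


# --- structure-level encoding ----------------------------------------


def int_coords(structure: Structure) -> np.ndarray:
    """All atom coordinates as (n_atoms, 3) int64 in 0.001 Å units."""
    c = structure.coords()
    if np.any(c < COORD_MIN) or np.any(c > COORD_MAX):
        raise RangeError("coordinate outside the representable range")
    return np.rint(c * 1000.0).astype(np.int64)


def int_bfactors(structure: Structure) -> np.ndarray:
    b = structure.bfactors()
    if np.any(b < BFACTOR_MIN) or np.any(b > BFACTOR_MAX):
        raise RangeError("temperature factor outside the representable range")
    return np.rint(b * 100.0).astype(np.int64)


def infer_bfactor_mode(structure: Structure) -> int:
    """0: one value for the whole structure; 1: constant within each
    residue; 2: per-atom values.  Compared at stored (0.01) precision."""
    if not structure.residues:
        raise ValidationError("empty structure")
    per_res = []
    for res in structure.residues:
        vals = {encode_bfactor_int(a.bfactor) for a in res.atoms}
        if len(vals) > 1:
            return 2
        per_res.append(vals.pop())
    return 0 if len(set(per_res)) == 1 else 1


def encode_residue_ranges(indices: list[int]) -> str:
    """Compact ``"1~10,12~12"`` encoding of strictly increasing indices."""
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValidationError("residue indices must be strictly increasing")
    if not indices:
        return ""
    runs = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append((start, prev))
        start = prev = i
    runs.append((start, prev))
    return ",".join(f"{a}~{b}" for a, b in runs)


def decode_residue_ranges(text: str) -> list[int]:
    if not text:
        return []
    out: list[int] = []
    try:
        for part in text.split(","):
            a, b = part.split("~")
            out.extend(range(int(a), int(b) + 1))
    except ValueError as exc:
        raise CorruptionError(f"bad residue-range field {text!r}") from exc
    if any(y <= x for x, y in zip(out, out[1:])):
        raise CorruptionError(f"residue ranges not increasing: {text!r}")
    return out


def _delta_reference_indices(structure: Structure) -> np.ndarray:
    """For each atom (flat chain order) the flat index of its delta
    reference; -1 for the very first atom."""
    refs = np.empty(structure.n_atoms, dtype=np.int64)
    offset = 0
    prev_c_flat = -1  # flat index of previous residue's C (or CA when ca_only)
    for res in structure.residues:
        names = res.atom_names()
        for j in range(len(names)):
            refs[offset + j] = prev_c_flat if j == 0 else offset + j - 1
        anchor = "CA" if structure.ca_only else "C"
        prev_c_flat = offset + names.index(anchor)
        offset += len(names)
    return refs


def delta_encode_atoms(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Return (first-atom absolute int coords (3,), per-atom deltas
    (n_atoms-1, 3) as int64 guaranteed to fit int16)."""
    ints = int_coords(structure)
    refs = _delta_reference_indices(structure)
    deltas = ints[1:] - ints[refs[1:]]
    if deltas.size and np.abs(deltas).max() > 32767:
        k = int(np.argmax(np.abs(deltas).max(axis=1)))
        raise DeltaOverflowError(
            f"coordinate delta at atom {k + 1} exceeds 2-byte range "
            f"(max |delta| = {np.abs(deltas).max()} milli-Å)")
    return ints[0].copy(), deltas


def delta_decode_atoms(structure_shape: Structure, first: np.ndarray,
                       deltas: np.ndarray) -> np.ndarray:
    """Inverse of :func:`delta_encode_atoms` given a structure skeleton
    (atom names laid out, coordinates ignored)."""
    n = structure_shape.n_atoms
    refs = _delta_reference_indices(structure_shape)
    ints = np.empty((n, 3), dtype=np.int64)
    ints[0] = first
    for i in range(1, n):
        ints[i] = ints[refs[i]] + deltas[i - 1]
    return ints


# --- binary packing ---------------------------------------------------


def _pack_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    if len(raw) > 0xFFFF:
        raise ValidationError("header string longer than 65535 bytes")
    return struct.pack("<H", len(raw)) + raw


class _Cursor:
    """Sequential reader over a decompressed payload with bounds checks."""

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise CorruptionError("truncated PDC payload")
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.take(1)[0]

    def u16(self) -> int:
        return struct.unpack("<H", self.take(2))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def string(self) -> str:
        try:
            return self.take(self.u16()).decode("utf-8")
        except UnicodeDecodeError as exc:
            raise CorruptionError(f"undecodable string field: {exc}") from exc

    def array(self, dtype: str, count: int) -> np.ndarray:
        itemsize = np.dtype(dtype).itemsize
        return np.frombuffer(self.take(itemsize * count), dtype=dtype).astype(np.int64)

    def expect_end(self) -> None:
        if self.pos != len(self.data):
            raise CorruptionError(
                f"{len(self.data) - self.pos} trailing bytes in PDC payload")


def _pack_common(structure: Structure, flags: int, bfactor_mode: int) -> bytearray:
    h = structure.header
    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    out.append(flags)
    out.append(bfactor_mode)
    for s in (h.title, h.compound, h.source, h.dbref, structure.chain_id,
              encode_residue_ranges(structure.residue_indices())):
        out += _pack_str(s)
    seq = structure.sequence.encode("ascii")
    out += struct.pack("<I", len(seq))
    out += seq
    return out


def _structure_flags(structure: Structure) -> int:
    flags = 0
    if structure.ca_only:
        flags |= FLAG_CA_ONLY
    elif structure.residues[-1].atom_names()[-1] == "OXT":
        flags |= FLAG_HAS_OXT
    return flags


def _skeleton(sequence: str, res_indices: list[int], chain_id: str,
              header: HeaderMeta, ca_only: bool, has_oxt: bool) -> Structure:
    """Structure with the right atoms laid out and zero coordinates."""
    residues = []
    last = len(sequence) - 1
    for i, (c, idx) in enumerate(zip(sequence, res_indices)):
        res_type = ONE_TO_THREE.get(c)
        if res_type is None:
            raise CorruptionError(f"bad one-letter code {c!r} in sequence")
        if ca_only:
            names = ["CA"]
        else:
            names = canonical_atom_order(res_type,
                                         is_last_residue=(i == last and has_oxt))
        residues.append(Residue(res_type, idx,
                                [Atom(n, np.zeros(3)) for n in names]))
    return Structure(chain_id=chain_id, residues=residues, header=header,
                     ca_only=ca_only)


def compress_lossless(structure: Structure, *, gzip_level: int = GZIP_LEVEL) -> bytes:
    """Pack a structure into the lossless binary container (GZIP-wrapped).

    Deterministic: identical input produces identical bytes.
    """
    structure.validate()
    mode = infer_bfactor_mode(structure)
    out = _pack_common(structure, _structure_flags(structure), mode)

    first, deltas = delta_encode_atoms(structure)
    out += first.astype("<i4").tobytes()
    out += deltas.astype("<i2").tobytes()

    ib = int_bfactors(structure)
    if mode == 0:
        bvals = ib[:1]
    elif mode == 1:
        bvals = np.array([encode_bfactor_int(r.atoms[0].bfactor)
                          for r in structure.residues], dtype=np.int64)
    else:
        bvals = ib
    out += bvals.astype("<i2").tobytes()
    return gzip.compress(bytes(out), compresslevel=gzip_level, mtime=0)


def read_preamble(cur: _Cursor) -> tuple[int, int, Structure]:
    """Parse magic, flags and the seven shared fields; return
    (flags, bfactor_mode, skeleton structure)."""
    if cur.take(3) != MAGIC:
        raise FormatError("not a PDC payload (bad magic)")
    version = cur.u8()
    if version != VERSION:
        raise FormatError(f"unsupported PDC version {version}")
    flags = cur.u8()
    mode = cur.u8()
    if mode not in (0, 1, 2):
        raise CorruptionError(f"bad B-factor mode {mode}")
    title, compound, source, dbref, chain_id, ranges = (cur.string()
                                                        for _ in range(6))
    seq_len = cur.u32()
    try:
        sequence = cur.take(seq_len).decode("ascii")
    except UnicodeDecodeError as exc:
        raise CorruptionError(f"undecodable sequence field: {exc}") from exc
    indices = decode_residue_ranges(ranges)
    if len(indices) != seq_len:
        raise CorruptionError(
            f"residue ranges cover {len(indices)} indices but sequence "
            f"length is {seq_len}")
    skel = _skeleton(sequence, indices, chain_id,
                     HeaderMeta(title, compound, source, dbref),
                     ca_only=bool(flags & FLAG_CA_ONLY),
                     has_oxt=bool(flags & FLAG_HAS_OXT))
    return flags, mode, skel


def _gunzip(data: bytes) -> bytes:
    try:
        return gzip.decompress(data)
    except (OSError, EOFError) as exc:
        raise FormatError(f"not a GZIP-wrapped PDC file: {exc}") from exc


def decompress_lossless(data: bytes) -> Structure:
    """Exact inverse of :func:`compress_lossless`."""
    cur = _Cursor(_gunzip(data))
    flags, mode, skel = read_preamble(cur)
    if flags & FLAG_LOSSY:
        raise FormatError("payload is lossy; use decompress_lossy")
    n_atoms = skel.n_atoms
    first = cur.array("<i4", 3)
    deltas = cur.array("<i2", 3 * (n_atoms - 1)).reshape(-1, 3)
    if mode == 0:
        bvals = cur.array("<i2", 1)
        per_atom_b = np.repeat(bvals, n_atoms)
    elif mode == 1:
        bvals = cur.array("<i2", skel.n_residues)
        per_atom_b = np.repeat(bvals, [len(r.atoms) for r in skel.residues])
    else:
        per_atom_b = cur.array("<i2", n_atoms)
    cur.expect_end()

    ints = delta_decode_atoms(skel, first, deltas)
    for atom, ic, ib in zip(skel.iter_atoms(), ints, per_atom_b):
        atom.coord = ic / 1000.0
        atom.bfactor = ib / 100.0
    return skel
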