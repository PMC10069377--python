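"""Lossy codec: quantized CA trace + quantized torsions.

The CA trace is stored as the first CA's absolute integer coordinates plus
per-residue 1-byte deltas in 0.1 Å units (integer-coordinate differences
divided by 100).  Every torsion angle x is mapped to one byte by
``f(x) = int(127/180 * x + 0.5)`` with downward (floor) rounding, so the
worst-case round-trip error is half a step, (180/127)/2 ≈ 0.709°.
Temperature-factor deltas are stored in 0.1 units (values x10).

Anti-drift rule: every CA and B-factor delta is taken against the
accumulated *reconstructed* previous value, not the original one, so the
quantization error of each residue stays within half a quantization step
(0.05 Å per axis / 0.05 B-factor units) no matter how long the chain is.

Decompression rebuilds the CA trace by cumulative sums, then delegates
full-atomic reconstruction (torsion-space build + three-residue fragment
fitting) to :mod:`pdc.rebuild`.  Undefined terminal torsions (phi_1,
omega_1, psi_n) are stored as code 0 and ignored at rebuild.
"""

from __future__ import annotations

import gzip
import math
import struct

import numpy as np

from .errors import DeltaOverflowError, FormatError, ValidationError
from .lossless import (FLAG_CA_ONLY, FLAG_HAS_OXT, FLAG_LOSSY, GZIP_LEVEL,
                       _Cursor, _gunzip, _pack_common, _structure_flags,
                       encode_bfactor_int, infer_bfactor_mode, int_coords,
                       read_preamble)
from .model import Structure
from .rebuild import rebuild
from .tables import sidechain_torsion_count
from .torsions import TorsionRecord, extract_torsions

TORSION_STEP = 180.0 / 127.0


def quantize_torsion(x: float) -> int:
    """Map an angle in (-180, 180] to a 1-byte code: floor(127/180*x + 0.5)."""
    return int(math.floor(127.0 / 180.0 * x + 0.5))


def dequantize_torsion(q: int) -> float:
    """Inverse map, code -> degrees (q * 180/127)."""
    return q * TORSION_STEP


def _quantize_deltas(values: np.ndarray, first: np.ndarray,
                     step: int, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Quantize successive differences of integer ``values`` to 1-byte codes
    in units of ``step`` raw integer units, referencing the reconstructed
    (not original) previous value.  Returns (codes, reconstructed ints)."""
    n = len(values)
    codes = np.zeros((n - 1,) + values.shape[1:], dtype=np.int64)
    recon = np.empty_like(values)
    recon[0] = first
    for i in range(1, n):
        d = values[i] - recon[i - 1]
        q = np.sign(d) * np.floor(np.abs(d) / step + 0.5)
        if np.any(np.abs(q) > 127):
            raise DeltaOverflowError(
                f"{what} delta at position {i} exceeds 1-byte range")
        codes[i - 1] = q
        recon[i] = recon[i - 1] + q.astype(np.int64) * step
    return codes, recon


def quantize_ca_delta(delta: float) -> int:
    """Quantize a per-axis CA-CA difference (Å) to a 1-byte code in 0.1 Å
    units (round half away from zero)."""
    q = int(math.copysign(math.floor(abs(delta) * 10.0 + 0.5), delta))
    if abs(q) > 127:
        raise DeltaOverflowError(f"CA delta {delta} Å exceeds 1-byte range")
    return q


def quantize_bfactor_delta(delta: float) -> int:
    """Quantize a temperature-factor difference to a 1-byte code in 0.1
    units (round half away from zero)."""
    q = int(math.copysign(math.floor(abs(delta) * 10.0 + 0.5), delta))
    if abs(q) > 127:
        raise DeltaOverflowError(f"B-factor delta {delta} exceeds 1-byte range")
    return q


def _ca_bfactor_ints(structure: Structure) -> np.ndarray:
    return np.array([encode_bfactor_int(r.atom("CA").bfactor)
                     for r in structure.residues], dtype=np.int64)


def compress_lossy(structure: Structure, *, gzip_level: int = GZIP_LEVEL) -> bytes:
    """Pack a structure into the lossy container (GZIP-wrapped).

    For CA-only input the torsion and non-CA blocks are omitted; a
    full-atomic input keeps all blocks and is reconstructed at
    decompression time.
    """
    structure.validate()
    mode = infer_bfactor_mode(structure)
    flags = FLAG_LOSSY | _structure_flags(structure)
    out = _pack_common(structure, flags, mode)

    ca_ints = int_coords(structure) if structure.ca_only else np.stack(
        [np.rint(r.atom("CA").coord * 1000.0).astype(np.int64)
         for r in structure.residues])
    ca_codes, recon_ca = _quantize_deltas(ca_ints, ca_ints[0], 100, "CA coordinate")
    out += ca_ints[0].astype("<i4").tobytes()
    out += ca_codes.astype("<i1").tobytes()

    if not structure.ca_only:
        torsions = extract_torsions(structure)
        backbone = np.zeros((len(torsions), 3), dtype=np.int64)
        chi_codes: list[int] = []
        for i, rec in enumerate(torsions):
            for j, ang in enumerate((rec.phi, rec.psi, rec.omega)):
                backbone[i, j] = 0 if ang is None else quantize_torsion(ang)
            chi_codes.extend(quantize_torsion(c) for c in rec.chis)
        out += backbone.astype("<i1").tobytes()
        out += np.array(chi_codes, dtype="<i1").tobytes()

    ca_b = _ca_bfactor_ints(structure)
    if mode == 0:
        out += struct.pack("<h", int(ca_b[0]))
    else:
        b_codes, recon_b = _quantize_deltas(ca_b, ca_b[0], 10, "B-factor")
        out += struct.pack("<h", int(ca_b[0]))
        out += b_codes.astype("<i1").tobytes()
        if mode == 2:
            nonca = []
            for res, rb in zip(structure.residues, recon_b):
                for atom in res.atoms:
                    if atom.name == "CA":
                        continue
                    d = encode_bfactor_int(atom.bfactor) - rb
                    q = int(math.copysign(math.floor(abs(d) / 10 + 0.5), d))
                    if abs(q) > 127:
                        raise DeltaOverflowError(
                            f"B-factor delta for atom {atom.name} of residue "
                            f"{res.res_index} exceeds 1-byte range")
                    nonca.append(q)
            out += np.array(nonca, dtype="<i1").tobytes()
    return gzip.compress(bytes(out), compresslevel=gzip_level, mtime=0)


def decompress_lossy(data: bytes) -> Structure:
    """Decode a lossy payload: recover the CA trace and B-factors by
    cumulative sums and (for full-atomic payloads) rebuild all other atoms
    from the stored torsions."""
    cur = _Cursor(_gunzip(data))
    flags, mode, skel = read_preamble(cur)
    if not flags & FLAG_LOSSY:
        raise FormatError("payload is lossless; use decompress_lossless")
    ca_only = bool(flags & FLAG_CA_ONLY)
    has_oxt = bool(flags & FLAG_HAS_OXT)
    n = skel.n_residues

    first_ca = cur.array("<i4", 3)
    ca_codes = cur.array("<i1", 3 * (n - 1)).reshape(-1, 3)
    ca_ints = np.empty((n, 3), dtype=np.int64)
    ca_ints[0] = first_ca
    np.cumsum(np.vstack([first_ca, ca_codes * 100]), axis=0, out=ca_ints)
    ca_trace = ca_ints / 1000.0

    torsions: list[TorsionRecord] | None = None
    if not ca_only:
        backbone = cur.array("<i1", 3 * n).reshape(-1, 3)
        n_chi = sum(sidechain_torsion_count(r.res_type) for r in skel.residues)
        chi_flat = cur.array("<i1", n_chi)
        torsions = []
        pos = 0
        for i, res in enumerate(skel.residues):
            k = sidechain_torsion_count(res.res_type)
            rec = TorsionRecord(
                phi=None if i == 0 else dequantize_torsion(backbone[i, 0]),
                psi=None if i == n - 1 else dequantize_torsion(backbone[i, 1]),
                omega=None if i == 0 else dequantize_torsion(backbone[i, 2]),
                chis=[dequantize_torsion(q) for q in chi_flat[pos:pos + k]])
            pos += k
            torsions.append(rec)

    if mode == 0:
        b0 = struct.unpack("<h", cur.take(2))[0]
        res_b = np.full(n, b0, dtype=np.int64)
    else:
        b0 = struct.unpack("<h", cur.take(2))[0]
        b_codes = cur.array("<i1", n - 1)
        res_b = np.cumsum(np.concatenate([[b0], b_codes * 10]))
    per_atom_b: np.ndarray | None = None
    if mode == 2 and not ca_only:
        vals = []
        nonca = cur.array("<i1", skel.n_atoms - n)
        pos = 0
        for res, rb in zip(skel.residues, res_b):
            for name in res.atom_names():
                if name == "CA":
                    vals.append(rb)
                else:
                    vals.append(rb + nonca[pos] * 10)
                    pos += 1
        per_atom_b = np.array(vals, dtype=np.int64)
    cur.expect_end()

    if ca_only:
        for res, ic, ib in zip(skel.residues, ca_ints, res_b):
            res.atoms[0].coord = ic / 1000.0
            res.atoms[0].bfactor = ib / 100.0
        return skel

    bfac = (per_atom_b if per_atom_b is not None else res_b) / 100.0
    out = rebuild(skel.sequence, torsions, ca_trace, bfac,
                  add_oxt=has_oxt, res_indices=skel.residue_indices())
    out.chain_id = skel.chain_id
    out.header = skel.header
    return out


# --- container-level dispatch ----------------------------------------


def compress(structure: Structure, *, lossy: bool = False,
             gzip_level: int = GZIP_LEVEL) -> bytes:
    """Compress with the requested codec."""
    from .lossless import compress_lossless
    if lossy:
        return compress_lossy(structure, gzip_level=gzip_level)
    return compress_lossless(structure, gzip_level=gzip_level)


def decompress(data: bytes) -> Structure:
    """Decompress either container, dispatching on the flags byte."""
    from .lossless import decompress_lossless
    payload = _gunzip(data)
    if len(payload) < 5 or payload[:3] != b"PDC":
        raise FormatError("not a PDC payload (bad magic)")
    if payload[4] & FLAG_LOSSY:
        return decompress_lossy(data)
    return decompress_lossless(data)
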