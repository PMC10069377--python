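"""Lossless codec: integer scaling, delta chains, container round trips."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdc.errors import (CorruptionError, DeltaOverflowError, FormatError,
                        RangeError, ValidationError)
from pdc.fixtures import FixtureSpec, generate_structure
from pdc.io import to_pdb_string
from pdc.lossless import (compress_lossless, decode_residue_ranges,
                          decompress_lossless, delta_decode_atoms,
                          delta_encode_atoms, encode_bfactor_int,
                          encode_coord_int, encode_residue_ranges,
                          infer_bfactor_mode, int_coords)
from pdc.model import Atom, Residue, Structure


class TestScalarEncoding:
    @pytest.mark.parametrize("x, expected", [
        (0.000, 0), (12.345, 12345), (-999.000, -999000), (9999.0, 9999000),
    ])
    def test_coord_scaling(self, x, expected):
        assert encode_coord_int(x) == expected

    @pytest.mark.parametrize("x", [-999.001, 10000.0])
    def test_coord_out_of_range(self, x):
        with pytest.raises(RangeError):
            encode_coord_int(x)

    @pytest.mark.parametrize("b, expected", [(0.00, 0), (99.99, 9999),
                                             (-327.68, -32768)])
    def test_bfactor_scaling(self, b, expected):
        assert encode_bfactor_int(b) == expected

    def test_bfactor_out_of_range(self):
        with pytest.raises(RangeError):
            encode_bfactor_int(400.00)


class TestBfactorMode:
    def _chain(self, bfacs):
        residues = []
        for i, per_atom in enumerate(bfacs, start=1):
            atoms = [Atom("CA", np.array([3.8 * i, 0.0, 0.0]), b)
                     for b in per_atom[:1]]
            residues.append(Residue("ALA", i, atoms))
        s = Structure(residues=residues, ca_only=True)
        return s

    def test_uniform_is_mode_0(self):
        s = generate_structure(FixtureSpec(n_res=5, seed=1, bfactor_mode=0))
        assert infer_bfactor_mode(s) == 0

    def test_per_residue_is_mode_1(self):
        s = generate_structure(FixtureSpec(n_res=5, seed=1, bfactor_mode=1))
        assert infer_bfactor_mode(s) == 1

    def test_within_residue_variation_is_mode_2(self):
        s = generate_structure(FixtureSpec(n_res=5, seed=1, bfactor_mode=1))
        s.residues[2].atoms[-1].bfactor += 0.01
        assert infer_bfactor_mode(s) == 2


class TestResidueRanges:
    @pytest.mark.parametrize("indices, text", [
        (list(range(1, 11)), "1~10"),
        ([7], "7~7"),
        ([1, 2, 3, 8, 9], "1~3,8~9"),
    ])
    def test_examples(self, indices, text):
        assert encode_residue_ranges(indices) == text
        assert decode_residue_ranges(text) == indices

    @given(st.lists(st.integers(-5000, 5000), min_size=1, max_size=300,
                    unique=True))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, values):
        indices = sorted(values)
        assert decode_residue_ranges(encode_residue_ranges(indices)) == indices

    def test_non_increasing_rejected(self):
        with pytest.raises(ValidationError):
            encode_residue_ranges([3, 3])


class TestDeltaChain:
    def test_single_atom_has_no_deltas(self):
        s = Structure(residues=[Residue("GLY", 1,
                                        [Atom("CA", np.array([1.0, 2.0, 3.0]))])],
                      ca_only=True)
        first, deltas = delta_encode_atoms(s)
        assert list(first) == [1000, 2000, 3000]
        assert deltas.shape == (0, 3)

    def test_two_atom_delta_by_hand(self):
        atoms = [Atom("CA", np.array([1.000, 5.0, 5.0])),
                 Atom("CA", np.array([2.300, 5.0, 5.0]))]
        s = Structure(residues=[Residue("ALA", 1, [atoms[0]]),
                                Residue("ALA", 2, [atoms[1]])], ca_only=True)
        _, deltas = delta_encode_atoms(s)
        assert list(deltas[0]) == [1300, 0, 0]

    def test_overflow_is_a_hard_error(self):
        atoms = [Atom("CA", np.array([0.0, 0.0, 0.0])),
                 Atom("CA", np.array([40.0, 0.0, 0.0]))]
        s = Structure(residues=[Residue("GLY", 1, [atoms[0]]),
                                Residue("GLY", 2, [atoms[1]])], ca_only=True)
        with pytest.raises(DeltaOverflowError):
            delta_encode_atoms(s)

    def test_cumulative_deltas_conserve_absolutes(self, structure50_mode2):
        """Brute-force oracle: rebuilding absolute integer coordinates from
        the delta chain reproduces the direct integer encoding."""
        s = structure50_mode2
        first, deltas = delta_encode_atoms(s)
        assert np.array_equal(delta_decode_atoms(s, first, deltas), int_coords(s))


@pytest.mark.parametrize("mode", [0, 1, 2])
@pytest.mark.parametrize("ca_only", [False, True])
def test_container_round_trip(mode, ca_only):
    s = generate_structure(FixtureSpec(n_res=23, seed=11 + mode,
                                       bfactor_mode=mode, ca_only=ca_only))
    blob = compress_lossless(s)
    assert decompress_lossless(blob) == s
    assert compress_lossless(s) == blob  # deterministic bytes


def test_bfactor_block_length_per_mode():
    """Mode 0 stores one value, mode 1 one per residue, mode 2 one per
    atom — verified by exact payload length accounting."""
    for mode in (0, 1, 2):
        s = generate_structure(FixtureSpec(n_res=10, seed=4, bfactor_mode=mode))
        payload = gzip.decompress(compress_lossless(s))
        h = s.header
        strings = (len(h.title) + len(h.compound) + len(h.source)
                   + len(h.dbref) + len(s.chain_id) + len("1~10"))
        preamble = 6 + 6 * 2 + strings + 4 + s.n_residues
        coords = 12 + 6 * (s.n_atoms - 1)
        n_b = {0: 1, 1: s.n_residues, 2: s.n_atoms}[mode]
        assert len(payload) == preamble + coords + 2 * n_b


def test_ca_only_payload_round_trip():
    s = generate_structure(FixtureSpec(n_res=40, seed=8, ca_only=True))
    out = decompress_lossless(compress_lossless(s))
    assert out.ca_only
    assert all(r.atom_names() == ["CA"] for r in out.residues)
    assert out == s


class TestCorruption:
    def test_bad_magic(self):
        with pytest.raises(FormatError):
            decompress_lossless(gzip.compress(b"NOT A PDC FILE"))

    def test_not_gzip(self):
        with pytest.raises(FormatError):
            decompress_lossless(b"PDC\x01\x00\x00garbage")

    def test_truncated_payload(self, structure20):
        payload = gzip.decompress(compress_lossless(structure20))
        with pytest.raises(CorruptionError):
            decompress_lossless(gzip.compress(payload[:-10]))

    def test_corrupted_length_field(self, structure20):
        payload = bytearray(gzip.decompress(compress_lossless(structure20)))
        payload[6] = 0xFF  # title length prefix now overruns the payload
        with pytest.raises(CorruptionError):
            decompress_lossless(gzip.compress(bytes(payload)))


def test_pdc_smaller_than_gzipped_pdb():
    for n_res in (20, 60, 150):
        s = generate_structure(FixtureSpec(n_res=n_res, seed=n_res,
                                           bfactor_mode=1))
        pdb_gz = len(gzip.compress(to_pdb_string(s).encode(), compresslevel=9))
        assert len(compress_lossless(s)) < pdb_gz
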