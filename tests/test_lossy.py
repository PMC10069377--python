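"""Lossy codec: quantizers, torsion extraction, bounded round-trip error."""

import gzip

import numpy as np
import pytest

from pdc.errors import DeltaOverflowError, FormatError, ValidationError
from pdc.fixtures import FixtureSpec, generate_structure
from pdc.lossless import compress_lossless
from pdc.lossy import (TORSION_STEP, compress_lossy, decompress,
                       decompress_lossy, dequantize_torsion,
                       quantize_bfactor_delta, quantize_ca_delta,
                       quantize_torsion)
from pdc.model import to_ca_only
from pdc.tables import sidechain_torsion_count
from pdc.torsions import extract_torsions


class TestTorsionQuantizer:
    @pytest.mark.parametrize("x, code", [
        (0.0, 0), (180.0, 127), (-180.0, -127), (60.0, 42),
    ])
    def test_forward_examples(self, x, code):
        assert quantize_torsion(x) == code

    @pytest.mark.parametrize("code, angle", [
        (0, 0.0), (127, 180.0), (42, 42 * 180.0 / 127.0),
    ])
    def test_inverse_examples(self, code, angle):
        assert dequantize_torsion(code) == pytest.approx(angle, abs=1e-12)

    def test_round_trip_bound_on_dense_grid(self):
        xs = -180.0 + 360.0 * np.arange(1, 20002) / 20001.0
        codes = np.floor(127.0 / 180.0 * xs + 0.5)
        err = np.abs(codes * TORSION_STEP - xs)
        assert err.max() <= TORSION_STEP / 2 + 1e-9
        assert np.all(np.abs(codes) <= 127)


class TestDeltaQuantizers:
    @pytest.mark.parametrize("d, code", [(3.800, 38), (0.0, 0), (-1.234, -12)])
    def test_ca_delta_examples(self, d, code):
        assert quantize_ca_delta(d) == code

    def test_ca_delta_overflow(self):
        with pytest.raises(DeltaOverflowError):
            quantize_ca_delta(12.75)

    @pytest.mark.parametrize("d, code", [(0.00, 0), (1.23, 12), (-0.55, -6)])
    def test_bfactor_delta_examples(self, d, code):
        """Round half away from zero: -5.5 tenths becomes -6."""
        assert quantize_bfactor_delta(d) == code


class TestExtractTorsions:
    def test_build_then_measure_consistency(self, structure20):
        """Torsions measured on a generated ideal-geometry chain match the
        angles it was built from (checked against the file-precision
        rounding of coordinates)."""
        from pdc.fixtures import sample_torsions
        from pdc.rebuild import build_torsion_space_model

        rng = np.random.default_rng(123)
        tors = sample_torsions("AEKFL", "helix", rng)
        s = build_torsion_space_model("AEKFL", tors)
        got = extract_torsions(s)
        for want, rec in zip(tors, got):
            for a, b in [(want.phi, rec.phi), (want.psi, rec.psi),
                         (want.omega, rec.omega), *zip(want.chis, rec.chis)]:
                if a is None:
                    assert b is None
                else:
                    assert b == pytest.approx(a, abs=1e-6)

    def test_terminal_torsions_undefined(self, structure20):
        recs = extract_torsions(structure20)
        assert recs[0].phi is None and recs[0].omega is None
        assert recs[-1].psi is None
        assert all(r.psi is not None for r in recs[:-1])

    def test_gly_has_no_chis(self):
        s = generate_structure(FixtureSpec(n_res=3, seed=1, composition={"G": 1}))
        assert all(r.chis == [] for r in extract_torsions(s))

    def test_chi_counts_match_residue_types(self, structure50_mode2):
        for res, rec in zip(structure50_mode2.residues,
                            extract_torsions(structure50_mode2)):
            assert len(rec.chis) == sidechain_torsion_count(res.res_type)

    def test_ca_only_rejected(self):
        s = generate_structure(FixtureSpec(n_res=4, seed=0, ca_only=True))
        with pytest.raises(ValidationError):
            extract_torsions(s)


class TestLossyRoundTrip:
    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_ca_trace_quantization_bound(self, mode):
        s = generate_structure(FixtureSpec(n_res=60, seed=20 + mode,
                                           bfactor_mode=mode, ca_only=True))
        out = decompress_lossy(compress_lossy(s))
        assert out.ca_only
        assert np.abs(out.ca_coords() - s.ca_coords()).max() <= 0.05 + 1e-9

    def test_anti_drift_on_long_chain(self):
        """Per-axis CA error stays within half a quantization step on a
        2000-residue chain — the error does not random-walk."""
        s = generate_structure(FixtureSpec(n_res=2000, seed=2, ca_only=True))
        out = decompress_lossy(compress_lossy(s))
        err = np.abs(out.ca_coords() - s.ca_coords())
        assert err.max() <= 0.05 + 1e-9
        # tail as tight as the head
        assert err[-100:].max() <= 0.05 + 1e-9

    def test_torsion_round_trip_bound(self, structure50_mode2):
        """Chi angles are intra-residue, hence invariant under the rigid
        per-residue fragment fit: they come back within half a quantization
        step (plus 0.001 Å coordinate rounding).  Backbone dihedrals span
        two residues whose fitted transforms differ slightly, so they carry
        a small extra perturbation on top of the quantization bound."""
        s = structure50_mode2
        out = decompress_lossy(compress_lossy(s))
        orig, dec = extract_torsions(s), extract_torsions(out)
        for a, b in zip(orig, dec):
            for x, y in zip(a.chis, b.chis):
                wrapped = abs((x - y + 180.0) % 360.0 - 180.0)
                assert wrapped <= TORSION_STEP / 2 + 0.05
            for x, y in [(a.phi, b.phi), (a.psi, b.psi), (a.omega, b.omega)]:
                if x is None:
                    continue
                wrapped = abs((x - y + 180.0) % 360.0 - 180.0)
                assert wrapped <= TORSION_STEP / 2 + 2.0

    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_bfactor_bound(self, mode):
        s = generate_structure(FixtureSpec(n_res=45, seed=30 + mode,
                                           bfactor_mode=mode))
        out = decompress_lossy(compress_lossy(s))
        assert np.abs(out.bfactors() - s.bfactors()).max() <= 0.05 + 1e-9

    def test_full_atomic_rmsd_small_on_ideal_input(self):
        s = generate_structure(FixtureSpec(n_res=80, seed=5, bfactor_mode=1))
        out = decompress_lossy(compress_lossy(s))
        err = np.linalg.norm(out.coords() - s.coords(), axis=1)
        rmsd = float(np.sqrt(np.mean(err ** 2)))
        assert rmsd < 0.25

    def test_mode0_structure_stores_single_bfactor(self):
        s = generate_structure(FixtureSpec(n_res=12, seed=6, bfactor_mode=0))
        out = decompress_lossy(compress_lossy(s))
        assert np.unique(out.bfactors()).size == 1
        assert out.bfactors()[0] == s.bfactors()[0]

    def test_lossy_smaller_than_lossless(self):
        for n_res in (20, 80, 200):
            s = generate_structure(FixtureSpec(n_res=n_res, seed=n_res,
                                               bfactor_mode=1))
            assert len(compress_lossy(s)) < len(compress_lossless(s))

    def test_dispatch_on_flags(self, structure20):
        assert decompress(compress_lossless(structure20)) == structure20
        out = decompress(compress_lossy(structure20))
        assert out.sequence == structure20.sequence
        with pytest.raises(FormatError):
            decompress_lossy(compress_lossless(structure20))


def test_payload_size_is_linear_in_layout():
    """Exact structural accounting of the lossy payload: 3 bytes of CA
    deltas + 3 torsion bytes + chi bytes + 1 B-factor byte per residue
    (after the fixed-size blocks)."""
    for mode in (0, 1, 2):
        s = generate_structure(FixtureSpec(n_res=14, seed=40 + mode,
                                           bfactor_mode=mode))
        payload = gzip.decompress(compress_lossy(s))
        h = s.header
        n, n_atoms = s.n_residues, s.n_atoms
        n_chi = sum(sidechain_torsion_count(r.res_type) for r in s.residues)
        strings = (len(h.title) + len(h.compound) + len(h.source)
                   + len(h.dbref) + 1 + len("1~14"))
        preamble = 6 + 12 + strings + 4 + n
        expected = preamble + 12 + 3 * (n - 1) + 3 * n + n_chi + 2
        if mode >= 1:
            expected += n - 1
        if mode == 2:
            expected += n_atoms - n
        assert len(payload) == expected


def test_ca_only_lossy_omits_torsion_blocks():
    full = generate_structure(FixtureSpec(n_res=30, seed=9, bfactor_mode=1))
    ca = to_ca_only(full)
    p_full = gzip.decompress(compress_lossy(full))
    p_ca = gzip.decompress(compress_lossy(ca))
    n = full.n_residues
    n_chi = sum(sidechain_torsion_count(r.res_type) for r in full.residues)
    assert len(p_full) - len(p_ca) == 3 * n + n_chi
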