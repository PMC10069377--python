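# Methods

## Scope and input contract

The codec targets the dialect of single-chain predicted protein models:
one polymer chain of the 20 standard amino acids, every residue complete
(OXT optionally on the last residue), no heteroatoms, no alternate
locations, no insertion codes, no hydrogens (stripped on read).  Inputs
violating the contract are rejected rather than coerced — silently mapping
a modified residue to its parent would corrupt the stored sequence, and
the residue-index range encoding has no slot for insertion codes.
Coordinates are meaningful at 3 decimals (Å) and temperature factors at
2 decimals, the precision of the fixed-width text formats the container
replaces; "lossless" always means exact at that precision.

Internally coordinates are float64 Å; the codec scales by 1000/100 and
rounds half away from zero at the container boundary.  For values that
originate from 3-/2-decimal text this is exact (IEEE parsing and
`int/1000` division both produce the correctly rounded nearest double),
while structures built in torsion space keep full precision until they
are written or compressed.

## Lossless codec

Within each residue, atoms are stored in a fixed canonical order
(backbone first, then the side chain walking outward; transcribed
literally in `tables.py` since it is not derivable from topology).  The
delta reference of an atom is its predecessor in that order; the first
atom (N) of each residue references the previous residue's carboxyl C,
~1.3 Å away across the peptide bond, and CA-only files chain CA→CA
(~3.8 Å).  All differences fit 2-byte integers with very large margin
(±32.767 Å); a larger difference — possible only for inputs far outside
the target dialect — is a hard `DeltaOverflowError`, never a silent
widening.  B-factor repetition is classified automatically: mode 0 (one
value per structure), 1 (one per residue — the typical pLDDT case), or
2 (one per atom), and only the non-redundant values are stored.
Author residue indices are run-length coded as text (`"1~10,12~30"`).
The payload is GZIP-wrapped at level 9 with zeroed mtime so identical
input yields identical bytes.  See `FORMAT.md` for the byte layout; byte
compatibility with other implementations of the same field layout is a
non-goal.

## Lossy codec

Stored per structure: the first CA's absolute integer coordinates; per
residue, three 1-byte CA deltas (0.1 Å units); per residue, φ/ψ/ω codes
under `f(x) = ⌊(127/180)x + 0.5⌋`; χ codes per the Dunbrack quadruple
definitions (0–5 per residue type); and B-factor deltas in 0.1 units.
Design choices the format description leaves open, fixed here:

* **Anti-drift referencing.**  Every CA and B-factor delta is computed
  against the accumulated *reconstructed* previous value, not the
  original.  Quantization error therefore never random-walks: each value
  is within half a step (0.05 Å per axis; 0.05 B-factor units) of the
  original for any chain length.  Referencing originals instead would
  grow the error as √n and make sub-0.1 Å Cα accuracy unreachable for
  long chains.
* **Rounding.**  The torsion map's downward-rounding `⌊·+0.5⌋` is given;
  the ÷100 and ×10 delta quantizers round half away from zero, fixed for
  determinism.
* **Undefined torsions.**  φ₁, ω₁ and ψₙ do not exist; they are stored as
  code 0 and ignored at rebuild.  The final carbonyl O (whose ψ is
  undefined) is placed trans (dihedral N–CA–C–O = 180°).
* **ω indexing.**  ω of residue *i* is the torsion of the peptide bond
  *entering* residue *i* (CA(i−1)–C(i−1)–N(i)–CA(i)).
* **Mode-2 B-factors.**  Non-CA atoms store their difference from the
  residue's (reconstructed) CA value, independently per atom.
* **OXT** carries no torsion field; it is rebuilt from ideal geometry,
  anti to the carbonyl O about the CA–C axis.

## Reconstruction

Decoding a full-atomic lossy payload rebuilds the chain in torsion space
(NeRF internal-to-Cartesian placement: residue 1 in a canonical frame,
then N/CA/C extension from ψ/ω/φ, O from ψ, CB from a chirality-fixing
improper of −122.69°, side chains from per-residue placement rules) and
then anchors it to the decoded CA trace: for each residue *i* the
three-residue window (i−1, i, i+1) — clamped to the first/last triple at
the termini — is superposed by its CAs onto the trace (Kabsch, SVD with
determinant guard) and the resulting transform is applied to all atoms of
residue *i*.  Windows overlap, so no tiling seams arise; the output CA is
the transform image of the model CA rather than the trace point, keeping
intra-residue geometry exactly ideal.  Chains of one or two residues fall
back to whole-chain fits (translation; minimal rotation aligning the
CA–CA vector — a two-point Kabsch problem is rotationally degenerate).

Ideal bond lengths and angles are Engh–Huber-style restraint values,
shipped as a literal table (`ideal.py`).  Proline's CG/CD are placed from
χ₁/χ₂ with ring-like internal coordinates and no closure minimisation;
planar rings close via fixed 0°/180° torsions.  Exact decimals matter
less than self-consistency: the generator and the decoder share one
table, and the fragment fit absorbs small restraint-set differences.
Consequences of this architecture, verified by the test suite: rebuilding
from a structure's own measured torsions and trace reproduces an
ideal-geometry chain to <10⁻³ Å, the pipeline is rigid-motion
equivariant to 10⁻⁶ Å, and under quantization noise all bonded distances
stay within 15 % of ideal.

## Synthetic study conditions

All tests and the acceptance script run on synthetic chains from
`fixtures.py`: sequences drawn uniformly from the 20 amino acids;
torsions from Ramachandran-region Gaussians (helix φ∼N(−60°,6°),
ψ∼N(−45°,6°); sheet φ∼N(−120°,12°), ψ∼N(135°,12°); a broad uniform coil
region; a mixed sampler switching segments with probability 0.08 per
residue); ω∼N(180°,1.5°); χ wells at −60°/60°/180° with 12° jitter.
B-factors follow an AR(1) walk (lag-1 correlation 0.9) mapped into
[20, 100] to mimic pLDDT smoothness, with adjacent-residue steps clipped
to ±11.5 so that, with per-atom noise (mode 2) and quantization drift,
deltas stay within the 1-byte budget — mirroring how confidence tracks
vary smoothly along real predicted models.  Structures are built with the
reconstruction's own ideal geometry, shifted into the printable
coordinate window, and rounded to file precision.

What this does and does not show: lossless round-trip exactness, the
quantization error bounds, and the size *orderings* (PDC < gzipped text;
lossy < lossless) are representative, since they do not depend on
conformational realism.  The measured lossy MAEs (~0.04 Å Cα, ~0.05 Å
non-Cα on the synthetic corpus; `scripts/acceptance.py` recomputes them)
are a lower bound on what real predicted models give: real models deviate
from any single ideal-geometry table, which the torsion-space rebuild
cannot represent, so their non-Cα error in particular is larger.
Published large-corpus figures for this family of codecs are a few
hundredths of an Å higher for Cα and 2–5× higher for non-Cα atoms.
Benchmark sizes were chosen to keep the default suite fast: ~200
structures of 1–2358 residues for the lossless sweep, a 50-structure
corpus of 20–250 residues for sizes and MAEs.

## Numerical choices and degenerate inputs

Dihedrals use the IUPAC sign convention with range (−180°, 180°];
coincident or collinear frame points raise `DegenerateGeometryError`
rather than returning junk.  Superposition requires ≥3 points at the
public API.  The CB improper and the NeRF torsion sign were validated
against an energy-minimised L-alanine conformer (the usual
PeptideBuilder-style constant of +122.69° encodes the opposite sign
convention and would build D-amino acids here).  Single-residue
structures compress to an absolute coordinate with no deltas; empty
structures are invalid everywhere.

## Known limitations

* Single chain only; no heteroatoms, ligands, waters, hydrogens, altlocs,
  insertion codes, or multi-model files — by design of the dialect.
* The lossy codec assumes near-ideal covalent geometry; models refined
  with different restraints lose that refinement on decode.
* Header preservation covers title/compound/source/dbref only; other
  mmCIF categories are dropped.  The mmCIF mapping writes each of the
  four fields verbatim into one representative item
  (`_struct.title`, `_entity.pdbx_description`,
  `_entity_src_nat.pdbx_organism_scientific`,
  `_struct_ref.pdbx_db_accession`).
* B-factor deltas beyond ±12.7 units between adjacent residues (rare but
  possible at order/disorder boundaries of real models) are a hard error
  in lossy mode rather than an escape code.
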