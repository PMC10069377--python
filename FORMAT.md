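# The `.pdc` container

A `.pdc` file is a GZIP stream (level 9, zeroed mtime, so identical input
yields identical bytes).  The decompressed payload is laid out as below.
All multi-byte integers are little-endian two's complement.  Strings are
UTF-8, prefixed by a 2-byte unsigned length.

This layout is this package's own design: the field *order* follows the
published description of the format, but the published work does not pin
down a byte-level encoding, so byte compatibility with other
implementations is explicitly out of scope.

## Preamble (both codecs)

| field            | type        | notes                                        |
|------------------|-------------|----------------------------------------------|
| magic            | 3 bytes     | `"PDC"`                                      |
| version          | u8          | `1`                                          |
| flags            | u8          | bit0 lossy, bit1 CA-only, bit2 final-residue OXT present |
| bfactor_mode     | u8          | 0 = one value/structure, 1 = one/residue, 2 = one/atom |
| title            | string      | verbatim header text                         |
| compound         | string      | molecule name + chain id                     |
| source           | string      | organism + NCBI taxon                        |
| dbref            | string      | UniProt accession / entry / mapped range     |
| chain_id         | string      |                                              |
| residue_ranges   | string      | e.g. `"1~10,12~30"`; consecutive runs of author residue indices (stored as text, not binary) |
| seq_length       | u32         | number of residues n                         |
| sequence         | n bytes     | one-letter codes, ASCII                      |

The atom layout of the whole file is derivable from the preamble alone:
sequence + the canonical per-residue atom order + the CA-only and OXT
flags determine every atom name and count, which is what makes the
name-free numeric blocks below decodable.

## Lossless blocks (flags bit0 = 0)

| field             | type                  | notes                                   |
|-------------------|-----------------------|-----------------------------------------|
| first_atom_coord  | 3 × i32               | first atom, 0.001 Å units               |
| coord_deltas      | 3 × (n_atoms−1) × i16 | x,y,z triplets in chain order, 0.001 Å  |
| bfactors          | k × i16               | 0.01 units; k = 1, n_res or n_atoms per mode |

Each delta is taken against the previous atom in canonical order within
the residue; each residue's first atom (N) is taken against the previous
residue's carboxyl C.  CA-only files chain CA to CA.

## Lossy blocks (flags bit0 = 1)

| field                | type              | notes                                 |
|----------------------|-------------------|---------------------------------------|
| first_ca_coord       | 3 × i32           | 0.001 Å units                         |
| ca_deltas            | 3 × (n−1) × i8    | 0.1 Å units, vs reconstructed prev CA |
| backbone_torsions    | 3n × i8           | φ, ψ, ω per residue; `f(x)=⌊127/180·x+0.5⌋`; undefined termini stored as 0 *(omitted when CA-only)* |
| chi_torsions         | Σχ × i8           | χ1..χ5 per residue, same map *(omitted when CA-only)* |
| first_ca_bfactor     | i16               | 0.01 units                            |
| ca_bfactor_deltas    | (n−1) × i8        | 0.1 units, vs reconstructed prev *(omitted when mode 0)* |
| nonca_bfactor_deltas | (n_atoms−n) × i8  | 0.1 units, each non-CA atom vs its residue's reconstructed CA value *(mode 2, full-atomic only)* |

## Worked example

A synthetic 2-residue Gly-Gly chain, B-factor mode 1, header fields
`"T"`, `"C"`, `"S"`, `"D"`, chain `A`, residues 1–2, first atom at
(10.000, 10.000, 11.373) Å, per-residue B-factors 51.02 / 48.84.
Decompressed payload (96 bytes):

```
50 44 43        magic "PDC"
01              version 1
04              flags: lossless, full-atomic, OXT present
01              bfactor mode 1
01 00 54        title  "T"        (len 1)
01 00 43        compound "C"
01 00 53        source "S"
01 00 44        dbref  "D"
01 00 41        chain "A"
03 00 31 7e 32  residue ranges "1~2"
02 00 00 00     sequence length 2
47 47           "GG"
10 27 00 00  10 27 00 00  6d 2c 00 00    first atom (10000, 10000, 11373)
b2 05  00 00  00 00       delta CA−N  = (+1458, 0, 0)      } 8 more
27 02  8e 05  00 00       delta C−CA  = (+551, +1422, 0)   } deltas
...                                                        } follow
ee 13  14 13              B-factors (5102, 4884)
```
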