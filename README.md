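# hbscreen

Screening toolkit for **selective, complementary hydrogen-bonding end-group
pairs** — DNA-nucleobase analogues intended as recognition units on
self-assembling polymer templates.

A molecular "letter" here is a planar aromatic heterocycle presenting an
ordered row of 1–3 hydrogen-bond sites: N–H donors (D) and pyridinic-N or
keto-O acceptors (A).  Letters are written as shorthand codes — capital
letters `H`/`N`/`O` for the sites, followed by the aromatic skeleton in
`h`/`p` (hexagon/pentagon) letters, e.g. `HNH-hh` (a D·A·D pattern on two
fused hexagons) or `OHO-h-p` (A·D·A).  Useful pairs must bind each other
(X···Y) much more strongly than any alternative (X···X, Y···Y, X···Z), which
the toolkit quantifies with the **binding-energy contrast**

* binary: `E_C = E_XY − (E_XX + E_YY)/2`, for an isolated complementary pair,
* generalized: `E_C = E_XY − max_Z {E_XZ, E_YZ}`, for multi-letter alphabets
  where every partner inside the system competes (as G·C competes with G·G,
  G·A, ... in DNA).

The pipeline:

1. **Pose enumeration** — all binding registers of two facing site rows,
   generated by shifting and flipping one pattern along the hydrogen-bond
   direction, with symmetry deduplication (two asymmetric three-site groups
   give exactly 10 registers: 4 one-contact, 4 two-contact, 2 three-contact).
   Selected registers can be realised as planar 3D starting geometries with
   a 2 Å H···acceptor placement and exported as annotated multi-frame XYZ.
2. **Energies** — either a transparent built-in *surrogate scorer* (primary
   D→A bond terms, Jorgensen-style diagonal secondary cross-terms,
   acceptor–acceptor lone-pair repulsion, and a planarity-gated
   amine-as-acceptor term), or **ingestion of CSV energy tables** from
   external quantum-chemistry runs (DFTB+/PSI4 style), including
   counterpoise-corrected `BE_relax`/`BE_rigid`.
3. **Selectivity statistics** — the symmetric best-pose binding matrix,
   contrast computations, canonical-pair classification (DDA···AAD and
   friends), candidate selection above a contrast threshold, band-wise best
   pairs with the energy-gap statistic, amine pyramidalization angles and
   the contrast/dihedral correlation.
4. **Alphabet mining** — all 2-letter and 4-letter alphabets (letter-disjoint
   selective pairs) inside sliding binding-energy windows (width 10 kcal/mol,
   step 5 by default), with a brute-force reference implementation.

A packaged deterministic 64-group roster and planted-alphabet synthetic
matrices support testing the whole pipeline at desk scale.

## Worked example

```python
from hbscreen import (load_roster, surrogate_matrix, SurrogateParams,
                      select_candidates, scan, WindowSpec)

roster = load_roster()                       # 64 end groups
M = surrogate_matrix(roster, SurrogateParams())
cands = select_candidates(M, threshold=5.0)  # binary contrast > 5 kcal/mol
top = cands[0]
print(len(cands), top.x, top.y, top.E_XY, top.E_C_binary, top.canonical)
print(scan(M, WindowSpec(width=10.0, step=5.0), threshold=5.0)
      .counts_table().to_string(index=False))
```

prints

```
355 HHH-h NNN-hhh 24.0 23.48 True
 lower  upper  n_2L  n_4L
  -5.0    5.0     0     0
   0.0   10.0     0     0
   5.0   15.0    93     0
  10.0   20.0   144     0
  15.0   25.0   121     0
  20.0   30.0    10     0
```

Reading: of 2080 unordered combinations, 355 hetero pairs are selective at
the 5 kcal/mol binary-contrast level, the strongest being the canonical
triple-bonded DDD···AAA pair `HHH-h`/`NNN-hhh` at 24 kcal/mol (its contrast
nearly equals its binding energy because planar pure donors and pure
acceptors barely form homo pairs).  Sliding 10-kcal/mol windows hold up to
144 two-letter alphabets but — on the unplanted surrogate assay — no
four-letter alphabet: every pure donor binds every pure acceptor, so
two pure pairs can never be mutually exclusive, and the surrogate's mixed
pairs homo-pair too well.  Synthetic matrices with planted 4L alphabets
(`hbscreen.synth_matrix`) provide positive controls.

The same pipeline from the shell:

```sh
hbscreen poses --x DDA --y AAD                   # 10 alignments, 4/4/2
hbscreen matrix --surrogate --seed 7 --out m.csv
hbscreen contrast --matrix m.csv --threshold 5
hbscreen alphabets --matrix m.csv --window 10:20 --k 2,4 --out alpha.json
hbscreen report --matrix m.csv
```

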