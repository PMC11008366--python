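# Methods

## Problem setting

The package screens candidate "letters" for hydrogen-bond-encoded molecular
recognition: planar aromatic end groups carrying an ordered row of 1–3
donor (N–H) and acceptor (pyridinic N, keto O) sites.  Good letters pair
strongly and selectively with a designated complement and with nothing
else.  Selectivity is measured by the binding-energy contrast, either
against the pair's own homo dimers (binary form) or against the strongest
competing interaction within a declared context set (generalized form).

## Register (pose) enumeration

Two site rows face each other antiparallel.  All initial configurations are
produced by shifting the second row along the first and optionally flipping
it; flipping both molecules is a rigid rotation of the complex and is
excluded.  For patterns of lengths *m* and *n* each flip state contributes
*m + n − 1* shifts with at least one facing contact, hence 2(m+n−1) raw
registers.  A contact is a facing site pair regardless of chemistry — a
D–D register still counts one contact — which reproduces the 4/4/2
one/two/three-contact census (10 total) for two asymmetric three-site
patterns.

**Facing convention.**  With `flip=False` the second pattern is presented
reversed, as two molecules facing each other read in opposite directions;
`flip=True` presents it as written.

**Deduplication.**  Two registers describe the same physical pose exactly
when they are related by an internal symmetry of one molecule: reversing a
palindromic pattern (palindromic under role *and* flavor) is a symmetry of
that site row.  For a palindromic second pattern, `(flip, s)` coincides with
`(not flip, s)`; for a palindromic first pattern, with `(not flip, m−n−s)`
(the flipped register read after rotating the whole complex 180°); two
single-site patterns are the degenerate case, leaving one register.  The
unflipped representative is kept and output is ordered by `(flip, shift)`.
The test suite verifies this against an exhaustive physical-layout
comparison oracle over every role-pattern combination of lengths 1–3.

## Geometry realisation

Monomer templates live in a canonical frame: planar (z = 0), sites on a
regular 3.0 Å pitch along +x, hydrogen-bond directions along +y.  A pose is
realised by rotating the second monomer 180° in-plane (`flip=False`) or
about the site-row axis (`flip=True`) and translating it so the first
donor→acceptor contact places the donor H exactly `gap` (default 2.0 Å)
from the acceptor atom; on commensurate templates every other
donor–acceptor contact then lands at `gap` to machine precision, and this
is verified at 10⁻⁶ Å.  Same-role facing registers carry no distance
constraint.  Poses with any intermonomer distance below 1.0 Å are flagged
as collided, never dropped.  Both the planarity tolerance (0.1 Å RMS) and
the collision threshold are arguments.

Toy geometries place, per site, a ring atom and the functional atoms with
standard bond lengths (N–H 1.01 Å, C=O 1.23 Å, ring C–N 1.34/1.47 Å).
Amino groups are pyramidalised by tilting the non-bonding hydrogen out of
plane by (1 − planarity) · 54.74°, so the pyramidalization analysis
recovers the planted angle exactly.  These templates emulate the *site
topology* of optimised heterocycles, not their true geometry: ring
connectivity, conjugation and substituent sterics are absent, so geometric
results carry over to real molecules only at the level of register
combinatorics and placement logic.

## Energies

Binding energies are positive for bound complexes:
`BE = E_X + E_Y − E_complex`.  From ingested quantum-chemistry tables the
package derives `BE_relax` (isolated relaxed monomers vs the
counterpoise-corrected complex energy) and `BE_rigid` (frozen in-complex
fragments); requesting either without its inputs is an explicit error,
never a silent zero.  Tables are CSV with per-row or per-file units
(1 hartree = 627.509474 kcal/mol); conflicting duplicate rows are rejected
with both row numbers named.

**Surrogate scorer.**  Standing in for semiempirical/DFT energetics, the
surrogate is an additive contact model (defaults in kcal/mol):

| parameter | default | meaning |
|---|---|---|
| `P_N` | 6.0 | primary D···N(pyridinic) bond |
| `P_O` | 5.0 | primary D···O(keto) bond |
| `S` | 1.5 | diagonal secondary cross-term magnitude |
| `beta` | 0.6 | donor-as-acceptor factor in D–D registers |
| `R_AA` | 1.0 | acceptor–acceptor lone-pair repulsion |
| `sigma_noise` | 0.0 | seeded Gaussian jitter |

Each facing D–A contact contributes `P_N` or `P_O`; each A–A contact
−`R_AA`; each D–D contact `beta · (1 − min(planarity)) · P_N` — zero for
fully planar (conjugated) amines, which is the surrogate's rendering of the
observation that planar pure donors barely homo-pair.  Every adjacent pair
of contacting registers exchanges two diagonal secondary cross-terms of
magnitude `S`, attractive between unlike roles, repulsive between like
roles, in the spirit of secondary electrostatic interaction models of
multiply hydrogen-bonded dimers.  The scorer is exactly symmetric under
swapping the two groups (noise included: the noise key canonicalises the
pose description from both ends) and bit-reproducible at `sigma_noise=0`.
The defaults were chosen so the qualitative trends hold (near-zero
planar-donor homo pairs, keto weaker than pyridinic, triple bonds ~24
kcal/mol); the surrogate is *not* expected to reproduce external DFT
orderings such as the relative strength of DDA···AAD vs DDD···AAA.

**Best pose.**  Maximum binding energy among poses passing the planarity
predicate; ties prefer fewer contacts, then the lowest `(flip, shift)`
register (an arbitrary but fixed convention).  An empty passing set raises
an error carrying the rejected poses.

## Matrix, contrast, bands, pyramidalization

The binding matrix holds the per-pair best-pose energy, is symmetric by
construction, and records pose provenance per cell.  Candidate selection
keeps hetero pairs with binary contrast strictly above the threshold
(default 5 kcal/mol), sorted by binding energy.  Band reports use
half-open bands (last band closed) and report the best-contrast candidate
per band plus the maximum gap between consecutive sorted candidate
energies.  In the generalized contrast the context is an explicit
parameter; homo pairs always count among the alternatives.  Binary contrast
is the default for single-pair selection, the generalized form is used for
alphabets.

Pyramidalization of an amino nitrogen is the angle between the
N→third-substituent bond and the plane of (first substituent, N, second
substituent), substituents ordered heavy-atoms-first; it is 0° for planar
amines and arctan(√2) ≈ 54.74° for ideal tetrahedral geometry, and the
reported value is the mean over the listed nitrogens.  This formulation was
chosen over a four-atom improper dihedral because it is basis-independent
and exactly zero for planar groups.  Correlation between contrast and angle
is Pearson's r (scipy), with zero-variance inputs rejected as undefined
rather than returned as NaN.

## Alphabet mining

A k-letter alphabet is k/2 letter-disjoint pairs, each with binding energy
inside a closed window `[lower, lower+width]` and generalized contrast
above the threshold.  Conventions, each of which is an explicit option
because reasonable alternatives exist:

- **Context** defaults to the alphabet's own letters (a deployed 2L/4L
  system physically contains only those species); the whole roster is
  available as the stricter alternative.
- **Window membership** requires every pair of the alphabet in-window by
  default; a relaxed any-pair-in-window mode exists.
- Window edges are closed on both sides; ties at the edges are included.
- Letters with fewer than two hydrogen-bond sites are excluded (one bond
  cannot fix the mutual orientation); homo pairs are never alphabet pairs
  but always compete as alternatives.

The fast search enumerates in-window pairs and their disjoint
combinations; a brute-force oracle enumerates all letter subsets and all
perfect matchings and is held set-equal to the fast path on randomized
matrices in the test suite.  The sliding scan starts at the step-multiple
at or below the smallest observed hetero-pair energy and advances by the
step until the largest.

## Roster and synthetic data

The packaged roster has exactly 64 groups: the named vocabulary of the
screen (16 codes), five nucleobase stand-ins under fixture-convention codes
(see `NUCLEOBASE_CODES`; these encode Watson–Crick edges as site rows and
are conventions of this package), and deterministic fillers completing the
class census D, A, DA, DD, AA, DDD, AAA, DDA, DAD.  The census deliberately
over-weights 2- and 3-site groups (6 single-site, 29 two-site, 29
three-site) since single-site groups exist only to expose trends.

Planarity per group follows a deterministic rule: pure acceptors 1.0 (no
amino group); otherwise `0.45 + 0.18·n_rings − 0.12·(n_donors − 1)` plus a
0–0.1 code-keyed jitter, clipped to [0, 1] — larger π-systems planarise
amino groups, additional electron-donating amines pyramidalise them.  This
reproduces the qualitative ordering (e.g. `HH-hh-p` planar and selective,
`HHH-h` pyramidal and poor) without claiming quantitative angles.

Synthetic matrices are the surrogate matrix with optional *planted*
alphabets: planted pair cells are set to the requested energies and every
other interaction among the alphabet's letters is clamped to
`min(energies) − margin`, guaranteeing generalized contrast ≥ margin.
Infeasible requests (shared letters, conflicting cell assignments,
nonpositive margin) fail before any generation.  With `sigma_noise = 0` and
no planting the synthetic matrix equals the surrogate closed form; all
randomness is keyed by the spec seed plus stable per-pair digests, so
matrices are reproducible per seed and independent of roster order.

## What the tests do and do not show

Property tests cover the enumeration census and dedup oracle, surrogate
hand-sums, oracle equivalence of the alphabet search, planted-alphabet
recovery, contrast identities (binary ≥ generalized at two-letter context;
monotone decrease with context growth), pyramidalization closed forms and
the negative contrast–angle correlation on a planarity sweep.  Problem
sizes are chosen for the desk: random matrices of 8–12 groups for oracle
equality (the oracle is exponential in k), the full 64-group roster for
matrix-level checks.  Passing says the combinatorics, statistics and
plumbing are correct; it says nothing about the accuracy of any external
energy model.  The reproduction of the published DFTB+D3H5 alphabet tallies
requires the externally published binding matrix at
`data/external/dftb_d3h5_matrix.csv` and is reported as an explicit failure
when that file is absent.

## Known limitations

- The surrogate ignores cooperative polarisation, steric clashes beyond a
  hard distance flag, long-range electrostatics and solvent/substrate
  effects; it is a screening stand-in, not a potential.
- Toy geometries are site-topology templates, not chemical structures; no
  tautomers, catemers or out-of-plane (stacked) poses are modelled.
- Band selection reports the best-contrast pair per band mechanically; a
  curated shortlist may legitimately differ near band edges.
- Geometry realisation assumes commensurate site pitches; irregular
  experimental geometries raise rather than silently approximating.
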