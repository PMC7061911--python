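# Methods

## Protein Block assignment

The 16-prototype table (labels *a*–*p*, 8 reference dihedrals each) is
transcribed from the structural-alphabet definition publication
(de Brevern, Etchebest & Hazout 2000, Proteins 41:271–287) — the same
table PBxplore distributes — and pinned by a sha256 checksum test. The
assignment window for residue *i* is (ψ<sub>i−2</sub>, φ<sub>i−1</sub>,
ψ<sub>i−1</sub>, φ<sub>i</sub>, ψ<sub>i</sub>, φ<sub>i+1</sub>,
ψ<sub>i+1</sub>, φ<sub>i+2</sub>); the score is the angular RMSD (each
difference wrapped to (−180°, 180°] before squaring — required for
correct behaviour near ±180°); ties resolve to the alphabetically first
label. The first/last two residues of a chain, and any residue whose
window touches a chain break or undefined torsion, are labelled *Z*.
*Z* never enters frequency normalisation; per-position support is
tracked separately, and positions with support 0 have undefined
N<sub>eq</sub>/ΔPB.

N<sub>eq</sub> uses the natural logarithm with 0·ln 0 ≡ 0, which gives
the limits 1 (single block) and 16 (uniform) exactly. Frequency vectors
are validated to sum to 1 within 1e−9.

## Structure input conventions

PDB parsing is delegated to gemmi. Residues missing any of N/CA/C are
dropped and counted; alternate locations keep the highest-occupancy copy
(ties: first occurrence); hydrogens and waters are ignored; each MODEL
yields its own chains. A C(i)–N(i+1) distance above 2.5 Å marks a chain
break (peptide bond ≈ 1.33 Å; the margin tolerates poorly refined
files). φ/ψ follow the IUPAC sign convention and are reported in degrees
throughout; torsions flanking breaks and termini are undefined. Insertion
codes order alphabetically after the bare residue number.

## Superposition and similarity

The optimal proper rotation is the least-squares (Kabsch) fit via
scipy's `Rotation.align_vectors`; reflections cannot occur. The default
atom set is Cα only — the common denominator of the various RMSD tools
in circulation, whose backbone-subset defaults differ; `backbone`
(N, CA, C, O) is available per mapping. Atom equivalence is always an
explicit mapping, monotone in both chains; segments of different length
(typically CDR3) are never force-mapped — unmapped residues are simply
absent from the profile. Per-region RMSD is reported in two labelled
modes: deviations of the region's residues under the single global fit
(mode `global_fit`), and an independent refit on the region alone
(`refit`, undefined below 3 mapped pairs). GDT-TS is approximated from
the single global superposition (mean over 1/2/4/8 Å of the percentage
of mapped Cα pairs within threshold) rather than the full per-threshold
maximal-subset search; the approximation is a documented lower bound.

## Disulfide geometry

Bridges are detected among cysteine SG pairs within 2.3 Å (covalent
S–S ≈ 2.05 Å plus refinement-noise margin; configurable), paired
greedily by increasing distance so each cysteine joins at most one
bridge. The five torsions along the Cα→Cα path
(χ1 = N–CA–CB–SG, χ2 = CA–CB–SG–SG′, χ3 = CB–SG–SG′–CB′,
χ′2 = SG–SG′–CB′–CA′, χ′1 = SG′–CB′–CA′–N′) are stored and printed in
that path order, with the N-terminal cysteine always first, so patterns
are deterministic; a zero torsion counts as '+'. Topology classes use the
cysteines' scheme positions: canonical (23 + 104), type 1 (CDR1 + CDR3),
type 2 (FR2 + CDR3; a cysteine at the FR2/CDR2 boundary counts as FR2),
intra-CDR3, other. Only sign patterns are classified; the 20-class
taxonomy and dihedral strain energy of the published disulfide
classification are out of scope.

## Regions, numbering, hallmarks

The default region table is the IMGT unique-numbering span set
(FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
FR4 118–128, half-open internally), shipped as an editable structure —
observed FR lengths vary by 2–3 residues between domains, so region
lengths are measured, never hard-coded. Assigning IMGT numbers to a raw
sequence is accepted from external numbering tools or a user table; the
built-in anchor interpolation (Cys23/Cys104) is explicitly labelled
heuristic and is not a substitute for numbering software. Pairwise
identity uses one fixed convention: columns gapped in both sequences are
excluded from the denominator, gap-vs-residue counts as mismatch.
Redundancy filtering is greedy in input order with an identity-threshold
join rule — deterministic and order-reproducible. DSSP strings are
consumed, never computed; `.` marks an alignment gap while `-` is the
DSSP coil class.

## Ensemble diversity

Per-position N<sub>eq</sub> over a model ensemble uses the PB frequency
across models. Positions count as conformationally diverse when
N<sub>eq</sub> > 1 + 1e−9 (the entropy of a delta distribution is 1 only
up to rounding); bins are half-open, lower-inclusive ([1,2), [2,3), …),
and positions at exactly 1 are excluded from the bins — both the
tolerance and the convention are configurable and labelled in output.
CDR anchors are the three residues on each side of a CDR; anchors
truncated by a terminus are flagged.

## Synthetic generators

Backbones are built in internal coordinates (NeRF placement) with ideal
bond geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard
backbone angles, ω = 180°); only φ/ψ vary, which is exactly what the PB
alphabet reads. A PB string prescribes each torsion up to four times
through overlapping prototype windows; prescriptions are reconciled by
circular mean, which is the least-squares-optimal realisation of the
string.

A consequence worth stating precisely: only prototypes whose own window
slots agree — *d* and *m*, the strand and helix, selected by a ≤15°
slot-spread criterion — are realisable as arbitrarily long homopolymers.
The 14 cap/coil letters prescribe mutually inconsistent torsions at
overlapping offsets, so no torsion series realises a long run of them;
they are realisable only in short runs (≤2) inside transition words.
The random-string sampler therefore draws homopolymers from {d, m} and
mixed strings as walks on a frequent-transition graph read off the
recurrent structural words of the immunoglobulin fold (`dddd`, `dehia`,
`dehjf`, `fklpc`, `cdddd`, `mmmm`); such walks round-trip
build→measure→assign at ≥90% per string, homopolymers exactly.

Two-state conformational hotspots are planted as local PB-word flips
(e.g. strand ↔ loop word `ehia`) with exact quota frequencies: torsion
offsets of ±40–60° at a single position do not change the assigned block
— the prototype basins are wide, which is the alphabet's robustness
working as intended — whereas a word flip gives exactly two assignment
states, so a 50/50 hotspot reads N<sub>eq</sub> = 2.0 and an 80/20
hotspot the closed-form exp(−(0.8 ln 0.8 + 0.2 ln 0.2)).

Sequence families are mutated from a random root at per-region rates
inverted analytically from the expected pairwise identity
m = (1−p)² + p²/18 (18 non-root, non-Cys alternatives), with planted
positions (hallmark tetrad, position 11, Trp41, Cys23/104, optional
extra-cysteine pairs) held fixed and accounted for in the inversion.
Each sequence mutates a fixed, Bernoulli-rounded number of free sites
per region — same expectation as per-site coin flips, far lower
variance — so realised median identities land within ±3 points of the
targets (FR 84/72/81/90%, CDR 28/25/18%) at the default n = 50 for any
seed. Region lengths default to FR1 25, CDR1 8, FR2 17, CDR2 8, FR3 37,
CDR3 12, FR4 11, the observed medians for VHH domains with a CDR3 that
fits the IMGT 105–117 span. Short regions quantise identity (CDR1's 8
columns step by 12.5%, so its best attainable median against the 28%
target is exactly 25.0%).

Cysteine-pair fragments are placed atom by atom along the
N–CA–CB–SG–SG′–CB′–CA′–N′ path, so prescribed disulfide torsions and
S–S distance are realised exactly (re-measured within 1e−4°).

Every generator is a pure function of its config including the seed;
identical configs give byte-identical output.

### What the generators do and do not emulate

They emulate the statistical structure the analytics consume: torsion
series with known PB content, ensembles with known two-state mixtures,
aligned families with controlled per-region conservation and planted
sequence features, disulfide geometries with prescribed signs. They do
not emulate side chains beyond Cys CB/SG, packing, solvent, real
loop-length variation within an alignment (families are gap-free), or
the error structure of comparative modelling software. Passing tests
therefore demonstrate correctness of the measurements and statistics on
known ground truth — not that any particular real VHH dataset would
reproduce a given published number; dataset-scale values depend on the
actual structure sets behind them.

## Report bundles

The three pipeline reports (sequence, structure, ensemble) only
orchestrate: every number in their TSVs is produced by a core-module
operation. Each bundle embeds the resolved config and a sha256 over the
input files, making reruns diffable; logging records the filtering
counts (sequences read, residues dropped, bridges found) at stage
boundaries.

## Problem sizes used in the automated checks

The acceptance-style tests use 100 round-trip strings of length 30 plus
1,000 oracle windows, 100 random pairs against a ~860-rotation grid
oracle, 100 random disulfide prescriptions, two 100-model ensembles of a
40-residue segment, and one 50-sequence family — sizes chosen so the
whole suite completes in well under a minute while every check still
exercises the full code path.

## Known limitations

- GDT-TS from a single superposition underestimates the full GDT search.
- The anchor-based numbering heuristic breaks on sequences whose first
  or last cysteine is not the conserved one; use real numbering software
  for production annotation.
- The builder guarantees round trips only for realisable PB strings (see
  above); arbitrary strings over the 16 letters are generally not
  realisable, a property of the alphabet itself.
- PB frequency comparison assumes the sets are mapped to common
  positions; no alignment of PB strings is performed.
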