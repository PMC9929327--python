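# Methods

## Scope and model

`topform` operates entirely in the deconvoluted neutral-mass domain of
top-down proteomics.  A proteoform-spectrum match (PrSM) is modelled as a
database segment (1-based inclusive coordinates in the parent protein), one
of four N-terminal forms, and up to two unexpected mass shifts, each with a
signed Δm in the search window [−500, +500] Da and a placement interval.
Charge states, isotope envelopes and fragment intensities are outside the
model: the package consumes (or simulates) output that a deconvolution and
search stage has already reduced to neutral monoisotopic masses.

The theoretical neutral mass of a proteoform is the sum of residue chain
masses plus one water, the N-terminal form delta, and all shift deltas.
Residue masses are derived at import time from packaged elemental
compositions and a packaged monoisotopic element table (CODATA/NIST values);
nothing is looked up externally.  The N-terminal forms are additive deltas on
the database segment: `NONE` (0), `NME` (−131.040485 Da, initiator-Met
excision; the sequence string retains the M), `NME_ACETYLATION`
(−131.040485 + 42.010565) and `M_ACETYLATION` (+42.010565).

Fragment ladders are neutral b-type prefixes (no water, plus the N-terminal
form delta) and y-type suffixes (plus one water), the ion series produced by
collisional dissociation of intact proteins.  A shift contributes to a ladder
value only when its placement interval lies entirely on that side of the
cleavage site; a shift straddling a site makes that value undefined for
matching, and the ladder API flags such sites invalid rather than guessing.

## Δm annotation

Frequency analysis of shifts runs on nominal values: Δm rounded
half-away-from-zero to the nearest integer dalton (so ±0.5 rounds away from
zero; binning is odd-symmetric).  Explanation against the modification table
uses a flat dalton tolerance, default 0.5 Da — the effective window implied
by nominal-mass comparison.

Three explanation kinds are searched independently:

* **single** — all table entries with |Δm − δ| ≤ tolerance, ranked by
  absolute mass error, ties broken by ascending accession;
* **pair** — all unordered pairs i ≤ j (an entry may pair with itself, e.g.
  two oxidations for +32 Da) with |Δm − (δᵢ + δⱼ)| ≤ tolerance; equivalent by
  construction to the brute-force double loop, which the tests also run as an
  oracle.  Adduct-category entries are excluded from pairs because adduct
  stoichiometry is handled separately;
* **adduct series** — |Δm − (n·δ_SDS − m·131.040485)| ≤ tolerance over
  1 ≤ n ≤ 3 and m ∈ {0, 1}, covering the dodecyl-sulfate artifact pattern on
  intact proteins (+266.155, +532.310, +401.270 Da).  The adduct composition
  C12H26O4S (266.155180 Da) follows the intact-MS artifact literature; it is
  not a community-database entry and is packaged under accession 0.

Site compatibility (allowed residues and termini) is reported as an advisory
flag on each candidate but never used to exclude: open-search annotation
ranks by mass agreement alone and is explicitly a hypothesis generator, not a
confident assignment.  The packaged table is a curated subset (21 entries:
the PTMs relevant to bacterial top-down data plus common artefacts); a
full-database export can be loaded from TSV or `unimod.xml`.

A net Δm above +500 Da (e.g. two SDS adducts, +532 Da) is representable only
as a two-shift proteoform, since each individual shift is window-bounded.
`nominal_bin` therefore accepts `window=None` for binning net multi-shift
sums in reports.

## Localization

Each observed fragment neutral mass is assigned to the nearest ladder value —
shifted or unshifted, prefix or suffix, any site — within a ppm tolerance
(default 15 ppm, a customary fragment tolerance for top-down search engines;
configurable).  Three guards keep ambiguous evidence from narrowing
intervals:

* observations outside tolerance of every ladder value are dropped (counted);
* an observation within tolerance of two assignments whose errors differ by
  less than 0.01 ppm is uninformative and excluded.  The margin is far below
  any instrument's mass accuracy; it exists because near-degenerate ladders
  occur structurally — e.g. a dehydration shift (−18.010565 Da) differs from
  a water loss by 3×10⁻⁷ Da, so a shifted suffix ladder can collide with the
  unshifted prefix ladder whenever the flanking residue multisets have equal
  mass;
* for two-shift proteoforms only subset-closed inclusion patterns are
  enumerated (a prefix cannot contain the right-hand shift without the
  left-hand one).

A single shift is localized by intersecting interval constraints: an
unshifted prefix at site i (or shifted suffix) proves the shift lies at
position ≥ i+1; a shifted prefix (or unshifted suffix) proves ≤ i.  The
result provably equals brute-force enumeration of all single-residue
placements, which the test suite runs as an independent mass-level oracle on
~10³ fuzzed instances.  Two shifts are localized by exactly that brute-force
scan over ordered placement pairs p1 ≤ p2 (vectorized over the L×L pair
grid), and each reported interval is the projection of all consistent pairs.
Contradictory evidence raises an error carrying a conflicting match pair
rather than returning an empty interval.

Only singleton intervals produce a residue call; anything wider is reported
as an interval and excluded from residue-level statistics (the ambiguity
rule).  Under initiator-Met excision, position 1 of the database segment does
not exist in the molecule, so an interval touching only positions 1–2
resolves to the first retained residue.

`support` on a localization result counts the fragment matches consumed by
the reduction — the same convention as counting the ions drawn over a
sequence in spectrum-inspection figures.

## FDR control

Decoys are reversed target sequences (composition- and length-preserving,
deterministic) with `DECOY_`-prefixed accessions; a seeded shuffle is
available as an option.  Scores are −log10 E-value.  The filter sorts by
descending score and estimates, at each threshold, FDR =
(#decoys ≥ t) / max(1, #targets ≥ t) — the plain count ratio, no +1
correction — accepting the largest target set with estimate ≤ q (default
0.01, PrSM level only; protein-level FDR is out of scope).  Thresholds never
split tied scores.  The filter is provably monotone in q and matches
exhaustive threshold enumeration, both property-tested; a 200-simulation
harness with false-target scores drawn from the decoy score distribution
checks that the realized false proportion among accepted PrSMs stays within
q + 3 binomial SE.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis layer
assumes, with defaults fixed to the emulated study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| fraction of modified PrSMs | 0.47 | measured modified-PrSM share |
| shift spectrum (share of modified) | 16 Da: 0.1015, 15 Da: 0.0611, −18 Da: 0.0297, 32 Da: 0.0132 | measured global profile |
| minor named classes | 42: 0.07, 28: 0.06, 14: 0.04, −2: 0.03, 80: 0.02, 266: 0.04 | common PTM/artefact masses at plausible minor shares |
| background | remaining ~0.53, uniform magnitude on [1, 499.5] Da, random sign | long tail of rare/unexplained shifts filling the ±500 Da histogram |
| two-shift share among modified | 8/2423 | measured count of double-shift PrSMs |
| N-terminal form mixture | NONE 0.70, NME 0.15, NME_ACETYLATION 0.10, M_ACETYLATION 0.05 | unmodified majority with a realistic processed-form minority (not a measured quantity) |
| fragment coverage per site/kind | 0.8 | dense but incomplete ladders |
| fragment noise | Gaussian, 2 ppm sd | Orbitrap-class accuracy |
| false targets / decoys | 0.02 / 0.02, scores U(0,4) vs true U(4,16) on −log10 E | well-separated null for FDR exercises |

Proteins are Met-initiated with otherwise uniform residue usage (lengths
uniform on [50, 200]); sites are drawn uniformly over residues compatible
with each class's site list; N-terminal truncations occur at rate 0.10.
Everything is driven by one `numpy` generator seeded from the config, and
outputs are byte-identical across runs.

What the generator does **not** emulate — and therefore what passing
recovery tests cannot certify about real data: realistic amino-acid
composition and homology, correlated fragment coverage (real coverage decays
toward the protein interior), intensity-dependent noise, co-eluting
near-isobaric proteoforms, deconvolution artifacts (harmonics, off-by-one
isotope errors), and search-engine score distributions.  Recovery results
demonstrate internal consistency of the pipeline, not instrument-level
performance.

Named fixtures (`mini47`: 100 PrSMs with exactly 47 modified, full
noise-free coverage; `two_shift`: 24 modified PrSMs, half double-shifted;
`adduct_series`: +266.155 / +532.310 / +401.270 proteoforms of one protein)
are generated deterministically at call time rather than checked in.

## Numerical choices and degenerate inputs

* Element masses are fixed package constants; residue masses are computed
  from composition once at import and cross-checked against an independent
  reference table in the tests (1e−6 Da).
* Rounding is half-away-from-zero everywhere a display integer is produced
  (nominal bins, percentages), so 47.25% prints as 47% and −0.5 bins to −1.
* Formula parsing accepts bare counts (`C2H2O`) and signed parenthesised
  counts (`H(-2) O(-1)`); unknown symbols are errors, never silently zero.
* PrSM tables, fragment sidecars and the truth ledger serialise floats via
  `repr`, making writer→reader→writer round trips byte-stable.
* Empty inputs are defined, not errors: header-only tables read as empty
  lists, empty populations give undefined (None) percentages, histogram of
  unmodified records is all-zero.
* The fragment matcher takes one match per observation; exact and sub-0.01
  ppm ties are counted and excluded (see Localization).
* The two-shift pair scan is O(L² + matches·L²) with boolean numpy grids,
  ~1 ms at L = 200.

## Problem sizes

The default test suite and the recovery checks run at the sizes the package
treats as its reference conditions: parameter recovery on 5000 PrSMs
(~2300 modified, ~1.1 M fragment observations at full coverage; ~25 s total),
oracle-equivalence fuzzing on ~10³ instances with L ≤ 15, and FDR
calibration over 200 simulated datasets.

## Known limitations

* At most two shifts per proteoform, mirroring the upstream search setting;
  three-way decompositions of a single Δm are not searched.
* Localization is combinatorial (minimal consistent interval), not
  probabilistic; no site-confidence score is produced.
* The pair search treats the modification table as site-free mass values;
  biological plausibility filtering is deliberately left to the reader of the
  advisory site flags.
* b/y ions only; c/z (ETD) ladders are not modelled.
* The packaged modification table is a subset; annotations against it are
  hypotheses and inherit the usual open-search caveats.
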