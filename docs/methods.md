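# Methods

## Model

A randomized CDR3 window is modelled as an ordered list of degenerate
codons `c₁ … cₙ` on the coding strand. The library sampling model is
uniform and positionwise independent: each concrete codon within the
expansion of `cᵢ` is equiprobable, and positions are independent. This is
exact for the combinatorics (the window is literally a cartesian product)
and is the standard idealization of oligonucleotide synthesis — it ignores
coupling-efficiency bias between bases on the synthesizer, which real
degenerate primers exhibit at the percent level.

Under this model everything factorizes:

* DNA diversity `D_dna = ∏ |expand(cᵢ)|`;
* stop-free protein diversity `D_prot = ∏ |sense-support(cᵢ)|`
  (exact because the scheme is a per-codon product — every combination of
  per-position residues is realized);
* stop-free fraction `∏ (1 − Pᵢ(stop))`;
* motif probability `P(pattern) = ∏ Pᵢ(allowedᵢ)`, with the per-position
  distribution either unconditional or conditioned on stop-free
  translation.

Motif probabilities default to the **conditional-on-full-length** form
because sequencing summaries count motifs among full-length clones; under
the six-codon NNS/MRN scheme the conditional XBBXBX probability is exactly
(10/16)³ = 24.41%, whereas the unconditional value is (10/16)³·(31/32)³ ≈
22.2%. Only the conditional convention reproduces the tabulated theoretical
percentage.

All probabilities are computed as exact rationals (`fractions.Fraction`)
and converted to floats at the API surface, so values like 6/16 and 2/961
are bit-stable. Only the standard nuclear genetic code is supported; the
code table and the IUPAC symbol table ship as plain-text package data.

## Scheme extraction from primers

The randomized window is defined as the *maximal run of non-ACGT symbols*
in the primer; exactly one such run is required and its length must be a
multiple of three. Fixed bases inside the randomized region are not
supported. Antisense primers are reverse-complemented before codon
splitting, and the fixed sequences flanking the window are retained as the
framework (FR3/FR4) anchors used for CDR3 extraction and scaffold
embedding.

## Library-size heuristic

`library_size_estimate` multiplies the theoretical diversity by the
observed fraction of unique sequences among sequenced full-length clones.
It is implemented verbatim as a saturation heuristic and documented as
such; no abundance-based richness estimator (Chao1 etc.) is substituted,
because the point is to reproduce the conventional QC number, not to
improve it.

## Clone analysis conventions

* A clone is **full length** iff both framework anchors are found by exact
  case-insensitive substring match, the window between them has length
  3n, is concrete DNA, and translates without a stop. Mismatch-tolerant
  anchor search is out of scope (the generator produces error-free reads;
  no sequencing-error model exists here).
* Uniqueness is at the CDR3 **DNA** level; protein-level uniqueness is
  reported alongside.
* Motif percentages use unique full-length sequences as the denominator
  (the convention of library QC tables).
* Position-frequency matrices report percent per residue per position,
  rows in a fixed order (A, D, N, R, C, Q, E, G, H, I, L, K, M, F, P, S,
  T, W, Y, V); columns sum to 100 by construction.
* Enrichment is tested with Fisher's exact test, two-sided by the
  point-probability rule (sum of all tables with fixed margins whose
  hypergeometric probability does not exceed the observed one), computed
  in exact rational arithmetic so ties are unambiguous. A chi-square test
  with continuity correction is available behind a method flag. At the QC
  sample sizes (tens to low hundreds) the exact test is the defensible
  default; both give p < 0.01 on the reference comparison.
* Percentages are rounded half-up to one decimal at presentation.

## Synthetic-data generator

The generator emulates a plate of randomly picked clones from a freshly
transformed library:

* CDR3 windows drawn uniformly per degenerate position, embedded between
  the framework flanks;
* **corruption** applied with probability `q = 1 − f/s`, where `f` is the
  target analyzer-reported full-length rate (default 0.873) and `s` the
  scheme's stop-free fraction, so the expected reported rate equals `f`
  (targets above `s` are rejected as unsatisfiable). Corruption modes mix
  equally by default: a 1-nt deletion in the upstream flank (breaks the
  anchor, emulating a frameshift), 3'-truncation before the downstream
  anchor, and an in-frame stop planted in the window. Real non-full-length
  clones are not characterized in this detail anywhere; the mix is an
  explicit stand-in.
* **biopanning** as one round of weighted resampling with replacement: a
  clone's weight is the product of the weights of the motif patterns it
  matches. For a single pattern with library fraction p₀ and weight w the
  expected selected fraction is p₁ = w·p₀/(w·p₀ + 1 − p₀), and the weight
  is recoverable as the odds ratio of p₁ against p₀. Sampling with
  replacement models clone picking from a plate, so duplicate sequences
  occur and exercise the uniqueness logic.

All randomness flows through a single numpy PCG64 stream with a mandatory
seed; output FASTA (headers carry `full_length`/`motifs` truth fields) and
truth CSV are byte-identical across runs and platforms. The generator does
**not** model phage amplification dynamics, multi-round panning kinetics,
avidity, sequencing error, or synthesis bias — so passing tests show that
the analysis recovers the parameters of this idealized process, not that
it is robust to real-data artifacts.

Simulation sizes used in the test suite: 10⁵ clones for Monte-Carlo
agreement checks (3 binomial SE bands), 5 × 10³ selections for
weight-recovery (±10%), and 200 pipeline replicates at the reference
sample sizes (67 selected vs 222 picked → ~189 unique full-length) for the
empirical power of the enrichment test at α = 0.01. With enrichment weight
w = 2.64 those sample sizes give an exact power of ≈ 0.72 (computable
directly from the two binomials and the exact test), which the replicate
study reproduces.

## Reactivity panels

ELISA reactivities are ordinal: absent, weak, moderate, strong, very
strong (−, ±, +, ++, +++ → 0–4). Interpretation rules formalize prose
conventions and live in a threshold table (auditable, overridable):

* binder ⇔ reference-heparin cell ≥ moderate;
* dependence of binding on a sulfate group (N, 2-O, 6-O), judged from the
  corresponding desulfated heparin: **essential** if absent, **partial**
  if weak, **non-essential** if ≥ moderate; missing antigens give
  *indeterminate*, not an error;
* overall class: `non_binder`; `high_sulfation` (all three dependencies
  essential); `moderate_sulfation` (all three determined, none essential);
  `pattern_specific` otherwise.

The 6-O call always carries a caveat flag: the 6-O-desulfated heparin
preparation retains residual 6-O sulfation, reported in two places as 23%
and as about 30%; the flag records both values without choosing. The two
packaged panel fixtures encode one explicit segmentation of the source
tables' run-on text; rows whose segmentation is ambiguous carry a
confidence note, and cells constrained by accompanying prose are fixed by
that prose. The kidney immunohistochemistry table ships as a descriptive
fixture only; no inference is built on it.

## Numerical and degenerate-input choices

* Exact integer counts throughout diversity calculus (no float overflow at
  10⁸-scale libraries); scientific formatting only at presentation, 3
  significant digits.
* A degenerate codon whose expansion is all stops has no conditional
  distribution (error), and a 2×2 table with a zero margin has no exact
  test (error); empty clone sets and empty panels are rejected.
* Odds ratios use the raw cross-product with ∞/0 conventions for empty
  cells, never a continuity adjustment.
* Lower-case and RNA-style (U) input is canonicalized; anchor matching is
  case-insensitive.

## Known limitations

* No codon-usage weighting or alternative genetic codes.
* No gapped or variable-length motif matching; no position-weight-matrix
  scoring.
* No V-gene annotation, chromatogram handling, or CDR3 clustering.
* The reactivity rules operate on ordinal levels from endpoint ELISA; no
  quantitative curve fitting or epitope structure prediction.
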