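# cdr3kit

Combinatorial design and sequence analysis of degenerate-codon antibody
CDR3 phage-display libraries, with a focus on heparin/heparan-sulfate
binding consensus motifs.

Synthetic scFv antibody libraries are often built by randomizing the
heavy-chain CDR3 loop with a degenerate oligonucleotide. When the goal is
an anti-heparan-sulfate library, the degenerate codons can be chosen to
bias the loop toward the heparin-binding consensus **XBBXBX** (B = basic
residue R/K/H, X = any residue). cdr3kit provides the calculus and the
analysis tooling around such a design:

* **IUPAC codon algebra** — expansion of degenerate codons, reverse
  complement, translation, and exact (rational-arithmetic) per-codon
  amino-acid distributions.
* **Library schemes** — derive the randomized window from a degenerate
  primer (sense or antisense) and compute exact DNA diversity
  `D_dna = ∏ᵢ |expand(cᵢ)|`, stop-free protein diversity
  `D_prot = ∏ᵢ |sense-support(cᵢ)|`, and the stop-free fraction
  `∏ᵢ (1 − Pᵢ(stop))`.
* **Motif patterns** — class-based patterns (`XBBXBX`, `GZZP(R/K)X`, …)
  with exact theoretical match probabilities
  `P(match | full length) = ∏ᵢ Pᵢ(allowedᵢ | sense)`.
* **Clone analysis** — anchor-based CDR3 extraction from clone FASTA,
  full-length/uniqueness summaries, residue-by-position frequency
  matrices, and motif enrichment by an exact two-sided Fisher test
  (point-probability rule, rational arithmetic).
* **Synthetic libraries** — a seeded generator with scaffold embedding,
  tunable non-full-length corruption, and biopanning emulated as
  motif-weighted resampling (`p₁ = w·p₀ / (w·p₀ + 1 − p₀)`).
* **Reactivity panels** — ordinal ELISA panels against modified heparins,
  with rule-based sulfation-dependence calls.

## Worked example

```python
>>> import cdr3kit as ck
>>> scheme = ck.xbbxbx_scheme()          # from the built-in antisense primer
>>> scheme.codons
('NNS', 'MRN', 'MRN', 'NNS', 'MRN', 'NNS')
>>> report = ck.diversity(scheme)
>>> report.dna_diversity, report.protein_diversity
(134217728, 1728000)
>>> round(report.stop_free_fraction, 4)
0.9091
>>> float(ck.codon_aa_distribution("MRN").mass("RKH"))   # basic chance at B
0.625
>>> xbbxbx = ck.parse_pattern("XBBXBX")
>>> round(100 * ck.theoretical_probability(xbbxbx, scheme), 1)
24.4
>>> est = ck.library_size_estimate(n_full=194, n_unique=189, report=report)
>>> ck.format_scientific(est.estimated_clones)
'1.31 x 10^8'
>>> result = ck.enrichment_test(selected=(31, 67), random=(44, 189))
>>> round(result.p_value, 6)
0.000569
```

Reading: the six-codon scheme spans 1.34 × 10⁸ DNA sequences encoding
1.73 × 10⁶ distinct stop-free hexapeptides; 62.5% of draws at a B position
(an MRN codon) are basic; 24.4% of full-length clones are expected to carry
the complete XBBXBX site. Sequencing 194 full-length clones of which 189
are unique suggests ~1.31 × 10⁸ realized clones (a crude
fraction-unique heuristic). Seeing the motif in 31/67 selected versus
44/189 randomly picked clones is significant enrichment (Fisher exact,
p ≈ 5.7 × 10⁻⁴).

A thin CLI mirrors the library:

```bash
cdr3kit diversity
cdr3kit motif-prob --pattern XBBXBX --pattern "GZZP(R/K)X"
cdr3kit simulate --n 10000 --seed 1 --out clones.fasta --truth-csv truth.csv
cdr3kit analyze --clones clones.fasta --patterns "XBBXBX,GZZP(R/K)X"
cdr3kit reactivity
```

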