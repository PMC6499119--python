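# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `gonadpi`. It states no empirical claim that the test
suite or the analysis drivers do not themselves compute.

## The synthetic world

Real gonadal small-RNA studies of non-model fish rest on inputs this
package cannot ship (sequencing libraries, curated miRNA/ncRNA/repeat and
known-piRNA databases), so all development and testing runs against a
generative model whose parameters mirror the data regime the analysis is
designed for:

- **Transcriptome**: `n_genes` random-composition transcripts, lengths
  uniform on `transcript_length_range` (default 150–2,500 nt, matching the
  hundreds-to-kilobase scale of assembled unigenes). Each transcript
  carries a 5′UTR/CDS/3′UTR gene model with fractions (0.1, 0.7, 0.2);
  spans partition the transcript exactly (rounding at the boundaries, ±1
  nt). Coordinates are 0-based half-open internally, 1-based closed in the
  emitted GFF3.
- **Contaminants**: mature miRNAs (20–24 nt, 80% 5′U), rRNA/tRNA/snRNA/
  snoRNA (60–120 nt) and repeats (60–200 nt) are generated as reference
  sets **and embedded verbatim, non-overlapping, into a reserved ~10% tail
  of "host" transcripts**. This reproduces a property of real assemblies —
  structural-RNA and repeat content is present in the transcriptome — and
  guarantees contaminant-derived reads pass the exact-mapping gate of the
  cascade. Contaminant reads are fragments (18–32 nt) of embedded sources.
- **piRNA pool**: `n_pirna` origins drawn uniformly from non-host
  transcripts; length from a 26–32 nt weight table peaking at 26–30 nt;
  antisense with probability 0.57 (the slight antisense excess seen in
  gonadal libraries). The 5′ base is forced to U(T) with probability
  `p_5prime_U` (default 0.8) and base 10 to A with probability
  `p_pos10_A` (default 0.6); the "else" branch draws uniformly from the
  three other bases so the realised marginal equals the configured
  probability exactly. Forced bases are **written back into the
  transcriptome before extraction**, so re-extracting any truth record's
  coordinates reproduces its sequence from the emitted FASTA. Overlapping
  origins can in principle overwrite each other's forced bases; at the
  default density ((2 forced bases × n_pirna) / genome ≈ 1%) the
  perturbation of the realised bias is far below the 3-SE recovery
  tolerance used in tests.
- **Sex classes**: ovary-only 0.44 / testis-only 0.44 / biased 0.06 /
  shared 0.06 — sex-specific expression dominates gonadal piRNA
  populations at roughly a 1:1 ovary:testis ratio. Biased sequences get
  true log₂FC ±2.
- **Counts**: per-library negative binomial with mean = (lognormal
  abundance weight, σ=1) × depth × sex factor and dispersion 0.2 (Poisson
  in the dispersion→0 limit). One-sex classes have mean 0 in the other
  sex, so their cross-sex counts are structurally zero.
- **Known-piRNA set**: 93 pool members planted as "known" plus 200
  shuffled decoys (shuffling guarantees exact-identity search has true
  negatives). 93 mirrors the scale at which cross-species piRNA homology
  survives an exact-match criterion.
- **Microarray**: three samples per sex × three replicate spots per probe.
  Spot intensity = background (mean 50, lognormal) + signal × 2^(±log₂FC/2)
  × lognormal noise (CV 0.1). A configurable probe fraction (default 10%)
  receives inflated replicate noise (CV 0.6) to exercise the CV filter.
  Sex-specific probes hybridise at a 2% cross-hybridisation floor in the
  other sex rather than exactly zero: single-channel arrays never measure
  a true zero, and observed sex-specific probes show large-but-finite
  fold changes. Without this floor the replicate CV in the silent sex is
  undefined/huge and the CV filter would discard every sex-specific probe.

What the generator does **not** emulate: sequencing error (reads are
emitted at Q40, with an optional fixed low-quality fraction for QC tests),
adapter read-through beyond an optional fixed suffix, positional
composition structure of real transcriptomes, multi-mapping families /
piRNA clusters, and array spatial artefacts. A green recovery test
therefore establishes internal consistency of the pipeline under the
stated statistical structure, not performance on real libraries.

## Annotation cascade

Exact matching (0 mismatches, end-to-end, both orientations) replaces
short-read alignment; a 12-mer seed dictionary with full verification
makes the hit set identical to a brute-force scan (property-tested).
Labels are assigned by database priority — conserved miRNA, then
rRNA/tRNA/snRNA/snoRNA, then repeat, then novel miRNA, then piRNA
candidate (26–32 nt), then other — with exactly one label per mapped read;
unmapped reads are reported separately. Percentages are reported half-up
at 2 decimals, and label counts partition the mapped total exactly.

The novel-miRNA test is an acknowledged simplification of dedicated
precursor tools: ±70 nt of transcript context around the hit is folded by
Nussinov dynamic programming (Watson–Crick + GU wobble, minimum loop 3),
and the read is called novel-miRNA when the window reaches ≥18 pairs and
the read lies wholly within one arm (no optimal-structure pair has both
ends inside the read). Random ~160 nt windows routinely exceed 18 pairs,
so the arm condition does most of the discrimination; about half of
random mapped 18–25 nt fragments still pass, which bounds cascade
recovery at (1 − ~0.5 × fraction of such reads). At the default class mix
this costs ~1–2% and overall recovery stays above 95%. Thresholds (18
pairs, 70 nt context) are configurable.

## Classifier

The k-mer scheme is a linear score over concatenated k-mer frequency
blocks, k = 1..5 (1,364 features; each block sums to 1; windows with
non-ACGT bases are excluded from numerator and denominator). Weights are
signed Fisher ratios `sign(Δm)·Δm²/(v⁺+v⁻+ε)` with ε = 10⁻⁹; variances
use ddof = 1; the threshold maximises Youden's J over training scores
(smallest maximiser on ties, so selection is reproducible). Models
serialise to JSON and round-trip bit-exactly. Training sets default to
generator draws (biased positives vs unbiased negatives); a FASTA mode
accepts curated sets.

**Known limitation (measured, and the reason one acceptance check is
red):** position-agnostic composition features cannot represent a purely
positional signal. Forcing 5′U at 0.9 and 10A at 0.7 shifts a sequence's
expected U/A content by less than one base against a binomial standard
deviation of ≈3 bases, so *any* weighting of these features is capped
near 0.67 held-out accuracy (logistic regression on the identical
features), while the Fisher weighting reaches ≈0.55 and the Bayes rule on
the two positions themselves reaches 0.825. This is why the
position-specific "static" scheme (per-position smoothed frequencies,
pseudocount 1.0 spread 0.25 per base, score Σ log(f/0.25)) clearly beats
the k-mer scheme on synthetic data (AUROC 0.84 vs 0.58 in the worked
example) — on real piRNA sets, where classes differ in overall
composition, the ranking is typically reversed. The benchmark harness
reports both AUROCs on a common held-out split rather than asserting a
winner.

## Expression

- Sequencing-side differential expression uses a two-sided Fisher exact
  test on [pooled count, library remainder] × [ovary, testis]. With two
  libraries per sex there is no useful within-group replication, so an
  exact conditional test on pooled counts is the deterministic stand-in
  for an unspecified count-model test; it ignores biological
  overdispersion and its P-values are anti-conservative in that respect.
  BH follows the step-up formula `padj_(i) = min_{j≥i} p_(j)·m/j`, capped
  at 1 (cross-checked against statsmodels).
- log₂FC pseudocounts: 0.5 counts (sequencing), 0.01 intensity (array),
  to keep ratios finite; library-size normalisation rescales each sex's
  pool to the mean total, a no-op for equal sizes.
- Microarray order of operations follows the processing narrative:
  subtract background (floor 0, floored spots counted and warned) →
  replicate CV = sd(ddof=1)/mean per sample, probe filtered when **any**
  sample's CV ≥ 0.3 (the strictest reading of an unstated aggregation
  rule; a zero mean gives CV = ∞ and filters) → quantile-normalize the 18
  spot columns (rank-wise means; ties receive the mean of the reference
  values at their tied ranks, making the transform idempotent) →
  per-sample replicate medians → per-probe one-way ANOVA across the two
  groups of three sample medians (identically zero groups short-circuit
  to F = 0, P = 1 rather than 0/0) → category calls. Two-group ANOVA
  equals the pooled-variance t test (F = t², same P), property-tested.
- Sex-biased probes are clustered on z-scored sample medians with
  average-linkage correlation distance cut to k = 10 clades (k reduced
  with a warning when fewer probes exist); the partition is deterministic
  given input order and invariant to row permutation up to relabelling.
- Cross-platform concordance is the Pearson r between sequencing and
  array log₂FC with the t-approximation P; constant vectors are reported
  as undefined rather than raising.

## Genes and enrichment

A gene is piRNA-generating when ≥1 predicted piRNA maps exactly; a piRNA
hitting several genes counts once in each. The sex partition
(ovary/testis/both) is disjoint by construction. Enrichment is the
upper-tail hypergeometric P(X ≥ k) per term with BH across terms and a
Padj < 0.05 flag; the background is the supplied gene universe and a
study gene outside it is an error, not a silent drop. Term-to-gene maps
are plain TSV inputs; generating them (protein-domain or homology
annotation) is upstream of this package.

## Numerical conventions

- DNA alphabet internally; U is display-only.
- Half-up rounding at 2 decimals for all reported percentages; every
  reported percentage is stored with its numerator and denominator.
- All randomness flows from one integer seed through per-stage
  `numpy.random.Generator` streams, so every artefact is reproducible
  byte-for-byte; reruns with an identical configuration hash produce
  identical reports.
- Multi-mapping reads keep all hits; the recorded primary hit is the
  lexicographically smallest (transcript id, offset, strand). Position 10
  is counted on the read's 5′→3′ sequence regardless of strand.
  Feature-assignment ties break CDS > 3′UTR > 5′UTR.
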