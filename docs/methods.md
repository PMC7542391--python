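# Methods

## Insertion dating

Each full-length LTR retrotransposon is dated from the divergence of its
two terminal repeats, which are identical at insertion. The twin repeats
are aligned globally with affine gap costs (defaults: match +1, mismatch
−1, gap open −4, gap extend −1, where "open" is the score of a gap's first
position; conventional nucleotide values, configurable). Of co-optimal
alignments the aligner's first enumerated one is reported; the estimate
depends only on the optimal score's column composition, which is stable in
practice at the divergences involved (< 0.15).

Distance uses pairwise deletion: columns containing a gap or N are
excluded, and p is the mismatch fraction of the remaining columns. Indels
carry no signal under the substitution-clock model, so no gap-aware
distance is attempted; an alignment with zero usable columns is an error,
not a zero. Jukes–Cantor correction K = −(3/4)·ln(1 − 4p/3) is the
default, matched to the simulator's substitution process; a Kimura
2-parameter option (transition/transversion split) is provided for real
data where the equal-rates assumption is doubtful. p ≥ 3/4 (or the K2P
log-domain equivalent) raises a saturation error and the element is
reported in a skipped list — never silently dropped — and accumulates in
the landscape's "undatable" tally.

Age is T = K/(2r) with r = 1.02 × 10⁻⁹ substitutions/site/year per
lineage; the factor 2 reflects independent accumulation on both repeats.
Elements lacking a terminal repeat are excluded from dating and listed as
skipped: solo LTRs cannot be dated by this construction.

The landscape bins each dated element's full span length by K, stacked by
superfamily. Bin width defaults to 0.01 substitutions/site, which
separates 10/30/50-My cohorts at the default r (K ≈ 0.02/0.06/0.10).
Conservation holds exactly: binned length plus undatable length equals
total element length. Note the per-element sampling noise: at 1000 aligned
sites the standard error of p is ≈ 0.008, comparable to the bin width, so
a cohort whose expected K falls near a bin edge peaks in either adjacent
bin; tests and the acceptance script therefore locate a cohort's mode to
within one bin width.

## The direct-repeat detector

A deliberately minimal stand-in for dedicated LTR-finding tools so that
synthetic genomes run end to end from raw FASTA: exact k-mer (default 13)
seed pairs grouped by diagonal, clustered, extended ungapped under an
X-drop rule (+1/−2, drop 15), and accepted when each repeat is ≥ 100 bp,
ungapped identity ≥ 0.85 and the inter-repeat gap is within (0, 20 kb].
Overlapping candidates resolve by identity, then length, then leftmost
position. It recovers planted elements to within ~25 bp of their true
boundaries and produces no calls on 100 kb of i.i.d. background at
defaults; it makes no claim to the sensitivity of purpose-built detectors
on real nested/fragmented repeats, and superfamily classification is not
attempted (labels are inputs).

## RIP scanning

Windows (default 1000 bp, advancing 500 bp; a trailing partial window is
kept if ≥ half a window) are scored by the product index TpA/ApT and the
substrate index (CpA+TpG)/(ApC+GpT), counting overlapping dinucleotides
and skipping any pair containing N. A window is RIP-positive only when
both thresholds hold (product > 1.61 AND substrate < 0.53). A zero
denominator makes an index undefined; undefined never satisfies a
threshold, which prevents spurious calls in low-complexity windows (an
(AT)ₙ tract has an enormous product index but no substrate index at all).
Positive windows merge into regions when they overlap or abut. Both
indices are invariant under reverse complement (TA and AT are their own
reverse complements; CpA↔TpG and ApC↔GpT swap within their sums), so
scanning is strand-agnostic. A composite value (product − substrate) is
emitted for plotting convenience with no threshold attached. The window
and step are scan conventions chosen to resolve element-scale (~6 kb)
features, not fitted quantities.

## Enrichment machinery

Fisher's exact test on 2×2 tables is the exact hypergeometric tail
(one-sided) or the sum of tables with point probability ≤ observed
(two-sided), with no continuity approximation; the test suite verifies it
against full enumeration with exact rational arithmetic on all 5550 tables
with every margin ≤ 12. Enrichment defaults to one-sided "greater"
(over-representation). Raw p-values are primary; Benjamini–Hochberg
q-values are emitted alongside. P-values are reported at full precision —
no 2.2 × 10⁻¹⁶ display floor is imposed, so bounds against conventionally
floored printed values are tested with ≤.

Gene-vs-LTR adjacency counts a gene once if any coding interval overlaps
any LTR region extended by the flank (default 1000 bp) on both sides,
half-open semantics, clipped at contig ends. For the expansion-subset test
the 2×2 table is built subset-vs-rest (exclusive): the subset's hits
against hits among the remaining genes; the inclusive construction gives
the same qualitative bound and both are exercised in tests.

The k×2 chi-square uses Pearson's statistic with margin-derived expected
counts, df = (r−1)(c−1), and a logged warning when any expected count is
below 5. Hit-table filtering implements thresholds on percent identity,
query coverage (100·alignment_length/query_length) and the table's
significance column; the 12-column dialect includes query length
explicitly since coverage is otherwise uncomputable. The significance
column is filtered as given, whatever convention (p or E) produced it.

## Composition accounting

Within a repeat category, intervals are merged before summing so duplicate
annotations count once; across categories, tracks are independent (a base
under both a LINE and a SINE annotation counts in each), which is why
per-category percentages need not sum to 100; the additional repeat-total
figure merges across categories and is a true genomic fraction. GC content
excludes N from numerator and denominator. N50 is the smallest length L
such that contigs ≥ L cover half the assembly. Display rounding is half
away from zero at one decimal, applied only at presentation; all internal
values are full precision. When an LTR-type table is built from externally
stated counts and lengths, its totals row is always the recomputed column
sum, with a warning if a stated margin disagrees.

## Synthetic genomes

The generator is the package's ground-truth instrument. Background is
i.i.d. sequence at a configurable GC (default 0.447, a repeat-rich fungal
value). Genes are multi-exon (default 3 exons; exon/intron lengths drawn
as 1 + Poisson(mean − 1) around means of 539/112 bp) with exon sequence at
a higher coding GC (default 0.61). Elements are built per cohort
specification: a random ancestral LTR with TG…CA termini, an internal
span (defaults give the ~5.9 kb full-length span typical of the motivating
genome), twin repeats mutated independently for age·r expected
substitutions each, a 4–6 bp target-site duplication copied to both
flanks. The clock is the exact finite-time Jukes–Cantor transition — each
site differs from the ancestor with probability (3/4)(1 − e^(−4μ/3)) —
so multiple hits are modelled and the JC-corrected estimator is unbiased
against the generator; no indels are simulated (indel handling is a
dating-stage gap policy, tested with hand-made alignments). The termini
are re-imposed after mutation (4 fixed sites per repeat; bias on a
1000 bp repeat is ≪ the sampling error). Optional RIP damage converts C→T
in CpA context and G→A in TpG context (the same event on the other
strand), each target firing independently at the configured intensity,
contexts read from the pre-mutation sequence in one pass.

Placement assigns features to the least-loaded contig and then positions
them by stick-breaking: the contig's slack is split into random gaps
around the features, guaranteeing non-overlapping placement whenever the
features fit, with a hard "genome too small" error otherwise. A single
seeded generator drives all draws in documented order; identical configs
produce byte-identical FASTA/GFF3/truth outputs.

What the generator does not emulate — and hence what passing tests do not
show about real genomes: nested and fragmented insertions, solo-LTR
recombination products, compositional heterogeneity and isochore-like
structure, indel evolution, rate variation among sites, and real RIP's
processivity and family-alignment structure. Recovery results on
synthetic data demonstrate estimator correctness under the stated model,
not detector sensitivity on real repeat landscapes.

## Problem sizes and verification

The test suite and acceptance script run simulations sized for exactness
of conclusions rather than realism of scale: age-recovery cohorts of 100
elements with 1000 bp repeats at 10/30/50 My on a ~3 Mb genome (mean
cohort age recovered within 10%, as binomial error predicts), RIP checks
on 100–200 kb sequences, oracle comparisons on enumerable inputs (all
margin-≤12 Fisher tables; 200 random alignment pairs ≤ 12 bp against an
independent three-state DP, itself validated by exhaustive alignment
enumeration at ≤ 4 bp). The published-assembly arithmetic (superfamily
shares, coverage fold, genome fractions, mean element length) is exact
and scale-free.

## Known limitations

Paired-LTR dating assumes neutrality and a constant clock; RIP-damaged
elements violate both (RIP inflates apparent divergence), so ages for
RIP-positive elements are upper bounds at best — the truth table records
which simulated elements were treated so this interaction can be studied.
Superfamily labels are consumed, never inferred. The chi-square machinery
tests marginal homogeneity only; no multi-genome normalization is
attempted. The flank-enrichment test inherits the usual caveats of
gene-set tests with correlated genomic features (clustering of both genes
and repeats can inflate significance).
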