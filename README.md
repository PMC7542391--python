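# ltrscape

Tools for quantifying how LTR retrotransposon activity inflates a fungal
genome: molecular-clock dating of individual insertions, genome-wide
scanning for repeat-induced point mutation (RIP), enrichment testing of
genes adjacent to LTR regions, and assembly/composition accounting — plus a
synthetic-genome generator that plants elements of known age so every stage
can be verified against ground truth.

The motivating system is *Ophiocordyceps sinensis* (the Tibetan-Plateau
caterpillar fungus), whose 119.2 Mbp assembly is ~82% repeat sequence,
dominated by Ty3/Gypsy and Ty1/Copia LTR retrotransposons. The package is
generic: any genome FASTA with GFF3 repeat/gene annotations works.

## The core model

A full-length LTR retrotransposon carries two long terminal repeats that
are identical at the moment of insertion and then diverge neutrally under
the host's substitution clock. For each element with both repeats present,
the twin repeats are globally aligned (affine gaps), the observed
proportion of differing sites *p* is computed with pairwise deletion of
gap/N columns, corrected for multiple hits with Jukes–Cantor

&nbsp;&nbsp;&nbsp;&nbsp;*K* = −(3/4) · ln(1 − 4*p*/3),

and converted to an insertion age

&nbsp;&nbsp;&nbsp;&nbsp;*T* = *K* / (2*r*),

with *r* = 1.02 × 10⁻⁹ substitutions · site⁻¹ · year⁻¹ per lineage by
default (the factor 2 because both repeats accumulate substitutions). A
Kimura 2-parameter correction is available behind a flag. Binning total
element length by *K* yields the repeat landscape — an insertion-activity
timeline stacked by superfamily.

RIP, the fungal defence that hypermutates repeats C→T at CpA sites, is
detected in sliding windows from two dinucleotide ratios: the product
index TpA/ApT (> 1.61) and the substrate index (CpA+TpG)/(ApC+GpT)
(< 0.53); a window is RIP-positive only when both criteria hold, and an
index with a zero denominator is undefined and never satisfies a
threshold. Gene-family enrichment next to LTR regions (±1 kbp flanks) uses
one-sided Fisher's exact tests against the genome background; multi-genome
category comparisons use a k×2 Pearson chi-square.

## Worked example

Simulate a two-contig genome with two element cohorts of known age, then
date the insertions:

```sh
cat > sim.yaml <<'EOF'
seed: 7
n_contigs: 2
contig_length: 300000
n_genes: 40
elements:
  - {superfamily: Gypsy, ltr_length: 1000, internal_length: 3900, age_years: 3.0e+7, copies: 12}
  - {superfamily: Copia, ltr_length: 1000, internal_length: 3900, age_years: 1.0e+7, copies: 10}
EOF
ltrscape simulate --config sim.yaml --out demo
ltrscape date-ltrs --fasta demo/genome.fa --gff demo/annotations.gff3 --out dated
head -4 dated/ages.tsv
```

```
element_id  superfamily  span_length  aligned_sites  p         K         T_years
ltr00002    Gypsy        5900         1000           0.065000  0.067991  33328811.9
ltr00003    Gypsy        5900         1000           0.063000  0.065804  32256953.8
ltr00004    Gypsy        5900         1000           0.056000  0.058201  28529869.9
```

Each row is one element: 1000 aligned twin-LTR sites, observed divergence
*p*, corrected divergence *K* and the resulting age — scattered around the
planted 30 My (the per-element standard error of *p* at 1000 sites is
about 0.008, i.e. roughly 4 My). The landscape table shows the two cohorts
as separate peaks, Copia around *K* ≈ 0.02 (10 My) and Gypsy around
*K* ≈ 0.06 (30 My):

```
K_low   K_high  Copia  Gypsy  total
0.0100  0.0200  41300      0  41300
0.0200  0.0300  17700      0  17700
0.0500  0.0600      0  35400  35400
0.0600  0.0700      0  29500  29500
```

`ltrscape stats` prints the assembly summary for the same inputs (genome
600 000 bp, N50 300 000, GC 46.5%, coding 10.9%, LTR track 129 800 bp);
`ltrscape rip-scan` and `ltrscape enrich` complete the workflow. Every
subcommand writes a `manifest.json` with input/output digests, and reruns
with the same seed are byte-identical.

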