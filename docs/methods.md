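# Methods

## The statistic and its assumptions

The differentiation index (DI) of a biallelic or multiallelic site is
the largest absolute difference in nucleotide proportions between two
pools, computed over A/C/G/T reads only. It is a read-level statistic:
it assumes reads within a pool are exchangeable draws from the pool's
allele pool, which is exactly the situation pooling creates and exactly
where it breaks — when individuals are unequally represented (expression
differences, library effects), the effective number of sampled allele
copies is smaller than 2N and DI estimates at shallow depth are inflated
toward spurious differentiation. The pipeline's answer is not a model-
based correction but a filter: require a minimum read count in *both*
pools and inspect how results respond as the threshold sweeps 8–30.

DI properties relied on throughout: DI ∈ [0, 1]; symmetric in pools;
invariant to scaling a pool's counts (depends only on proportions);
DI = 1 iff some nucleotide is fixed-present in one pool and absent in
the other; undefined when a pool has no A/C/G/T reads (such sites keep
their SNP call but are excluded from DI summaries — a pool with only N
calls carries no frequency information).

## Pileup decoding and filters

The decoder implements the full mpileup base-column grammar. Decisions
that shape the counts:

* Indels (`+k<seq>`/`-k<seq>`) are consumed and ignored; `*` (deleted
  base) and `<`/`>` (reference skips from spliced alignments) contribute
  to no depth figure. Declared pileup depth may therefore exceed the
  reconstructed total; reconciliation warns rather than fails.
* N calls count toward per-pool total depth (and hence the
  minimum-reads filter) but are excluded from allele-frequency
  numerators and denominators.
* Positions whose base columns encode no aligned nucleotide in any pool
  (spliced-alignment gap positions) are removed before any counting.
  The gap filter runs before raw-SNP counting; the alternative order is
  observationally equivalent for every downstream statistic except the
  raw-SNP total, and filtering first keeps the site stream clean.
* Coordinates are 0-based half-open internally; pileup (1-based) and
  GTF (1-based inclusive) are converted at I/O boundaries only.
* Base qualities are parsed and discarded — no base-quality filter is
  part of the analysis.

SNP calling uses counts pooled across both pools for allele ranking and
minor-allele frequency (the upstream pileup combines both libraries);
ties in allele counts break alphabetically so the minor allele is
deterministic. Thresholds (MAF ≥ 0.05, ≥ 3 minor-allele reads,
DI ≥ 0.9, sweep 8–30, ±2,000 bp flanks) live in `PipelineConfig` as
overridable defaults.

## Annotation

Introns are not taken from the GTF but inferred per transcript as the
gaps between consecutive exons, so a transcript with k exons contributes
exactly k−1 introns. Classification is position-level and strand-blind
(pileup positions are strandless): *exon* or *intron* only when all
overlapping features agree and belong to one gene; overlap with multiple
genes, or with both exons and introns of one gene, is *genic-ambiguous*;
otherwise *intergenic*. "Nearest feature" means nearest exon or intron;
gene spans (union of a gene's exons) are used only for the ±flank
expansion count. Book-ended adjacency counts as distance 1 — the
convention that makes the minimum observable distance 1 bp, matching
`bedtools closest -d`. Chromosomes with no features at all yield
intergenic positions with *undefined* distance, excluded from distance
distributions, as are chromosomes on the unplaced-contig exclusion list
(`_random`, `chrUn` name patterns by default).

## The generator

`simulate_truth` → `synthesize_pileup` emulates the study design stage
by stage; defaults are the emulated conditions and are not tuned per
test:

| parameter | default | what it emulates |
|---|---|---|
| pools × individuals | 2 × 8 diploid | subspecies pools |
| site classes | shared 0.97 / divergent 0.025 (δ = 0.5) / fixed 0.005 | low background differentiation with rare outliers |
| shared allele frequency | Beta(0.8, 0.8) | U-shaped frequency spectrum |
| expression weights | lognormal σ = 1 per transcript per pool | unequal individual representation |
| depth | NB(mean 12, size 8) per pool | normalized library, modest overdispersion |
| unspliced fraction | 0.2 × exon depth in introns | mRNA-enrichment carry-over (gives intron/exon depth ratio ≈ 0.2) |
| UTR overhang | 200 bp at exon depth | transcription beyond annotated exon ends |
| intergenic segments | 10/chromosome at 0.5 × depth | unannotated transcription |
| errors / N calls | 0.005 / 0.002 per read-base | sequencing noise |
| read lengths | Normal(313, 100) clipped at 40 | long-read pyrosequencing scale |

Reads sample an individual with replacement in proportion to the
segment's expression weights, then one of that individual's two allele
copies. Conditionally on the genotypes this makes reads iid Bernoulli
draws from the weighted pool frequency — the exact law used by the
enumeration oracle in the recovery tests (pool allele count ~
Binomial(2N, p)/2N compounded with Binomial(depth, realized frequency)).
A plain Binomial(depth, p) model would understate DI's sampling
variance, because it ignores the genotype-sampling layer that persists
at any depth.

Intron positions that draw zero reads are emitted as reference-skip
pileup lines (`<`/`>` only), so the gap filter has real work on every
simulated dataset; emitted base symbols use `.`/`,` and upper/lower
case with 50 % strand probability, and 5 % of reads carry `^q`/`$`
markers, to exercise the decoder's bookkeeping.

What the generator does **not** model: technology-specific error
profiles (homopolymer errors), chimeric reads, mapping error and
mapping-quality structure, linked sites/LD, and real expression-level
distributions. Passing tests therefore demonstrate correctness of the
counting, filtering and classification machinery under the stated
sampling assumptions — not robustness to alignment artifacts.

## Validation comparison

Genotype tables contribute two allele observations per non-missing
diploid call; missing cells reduce counts rather than dropping
individuals. The bundled 14-record comparison table uses the
within-country subspecies contrast as the validation DI (the record
whose genotyping was incomplete enters with validation DI 0.00, since
the typed samples showed no frequency difference); with that table the
depth-vs-DI-gap regression gives Pearson r = −0.58, p = 0.03 (two-sided
t, n − 2 df), computed with n = 14. Counts of validated differentiated
SNPs use strict inequality (DI > cutoff).

## Numerical and testing choices

* Mean DI is kept at full precision; rendered sweep tables round to 2
  decimals.
* Sweep rows exclude undefined-DI SNPs from all columns; an empty
  passing set reports mean DI as undefined (None/NaN), never 0.
* Test problem sizes: the standard scenario is 2 × 100 kb chromosomes
  (~43 k covered positions, ~450 truth sites), chosen so the full
  simulate→count→call→annotate chain runs in seconds; the
  depth-filter-bias check uses 4 × 500 kb so that ≥ 500 sites pass the
  16-read threshold and the expected bias reduction (~0.01–0.02 in mean
  DI) clears its sampling error several-fold.
* Oracles are independent of the paths they check: an event-based
  constructor and a regex tokenizer for the decoder, brute-force
  per-base scans for classification and distances, exact binomial
  enumeration for the no-differentiation null and for DI recovery,
  sums-based formulas for correlation/regression.

## Known limitations

* DI is a point estimate with no uncertainty interval; ranking by DI at
  a fixed cutoff (0.9) is the intended use, not significance testing.
* The annotation rule set resolves multi-transcript conflicts by
  exclusion (ambiguous category) rather than by any transcript
  prioritization, so exon/intron totals are conservative.
* Gene spans are exon-union spans; an Ensembl gene record whose
  annotated span exceeds its transcripts' union would give slightly
  different flank-expansion counts.
* The generator's truth DI for divergent sites is the intended
  frequency difference δ; realized genotype frequencies fluctuate
  around it, which is part of the measured estimator variance, not a
  bias.
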