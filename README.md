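# pooldiff

SNP discovery and allele-frequency differentiation between two pooled
samples sequenced as normalized cDNA libraries, with a synthetic-data
generator that lets the whole analysis run — with ground truth — on a
laptop.

## The problem

When two populations (here: two subspecies of a songbird with different
migratory strategies) are each sequenced as a *pool* of individuals,
reads, not individuals, are the sampling unit for allele frequencies.
Against a background of shared polymorphism, loci with large
between-pool frequency differences are candidates for divergent
selection. The pipeline implements that outlier scan for a pooled
transcriptome mapped to a related reference genome:

1. **Base counting.** Multi-sample `samtools mpileup` text is decoded
   into per-position, per-pool nucleotide counts. Insertions and
   deletions are ignored; ambiguous calls (N) count toward sequencing
   depth but never toward allele frequencies; positions spanned only by
   spliced-alignment gaps carry no aligned nucleotide and are removed.
2. **SNP calling.** A position with ≥ 2 nucleotides across the combined
   pools is a raw SNP; a *high-quality* SNP additionally requires the
   minor allele (second most common nucleotide) at frequency ≥ 0.05 in
   ≥ 3 reads.
3. **Differentiation index.** For pools 1 and 2 with nucleotide
   proportions *p*₁ᵦ and *p*₂ᵦ,

       DI = max over b ∈ {A,C,G,T} of | p₁ᵦ − p₂ᵦ |

   so DI = 0 for identical frequencies and DI = 1 when the pools are
   fixed for different alleles. SNPs with DI ≥ 0.9 are flagged as
   highly differentiated.
4. **Depth filtering.** Because individuals contribute unequally to a
   pool, shallow sites give biased DI estimates; SNPs are filtered by
   the minimum per-pool read count and the threshold is swept (8–30) to
   show its effect on SNP counts and the DI distribution.
5. **Annotation.** Covered positions are classified against an Ensembl
   GTF (introns inferred between consecutive exons) as exon / intron /
   genic-ambiguous / intergenic, with per-category depth and SNP
   density, nearest-feature distances for intergenic positions, and the
   gene gain from expanding gene spans by ±2,000 bp (uncharacterized
   UTRs).
6. **Validation.** Candidate SNPs re-genotyped in independent
   individuals get a genotype-based DI (same statistic on allele counts
   from diploid calls); regressing the pooled-minus-validation DI gap
   on per-pool depth quantifies how depth filtering controls bias.

The generator in `pooldiff.simulate` emulates the data-generating
process — two pools of 8 diploid individuals, shared/divergent/fixed
site classes, lognormal expression weights, negative-binomial depth from
a normalized library, unspliced (intron-covering) reads, UTR overhang,
sequencing errors and N calls — and emits pileup/GTF/FASTA plus truth
tables, so every stage is testable against ground truth.

## Worked example

```python
import io
import pooldiff as pdx

truth = pdx.simulate_truth(pdx.SimParams(seed=1))
buf = io.StringIO()
pdx.synthesize_pileup(truth, buf)
buf.seek(0)
sites = list(pdx.parse_pileup(buf))
snps = pdx.call_snps_from_sites(sites)
rows = pdx.threshold_sweep(snps, range(8, 31, 2), 0.9)
print(pdx.sweep_table(rows, decimals=2).head(5).to_string(index=False))
```

prints

```
 min_reads_per_pool  n_snps  mean_di  n_highly_differentiated
                  8      97     0.24                        0
                 10      61     0.25                        0
                 12      37     0.24                        0
                 14      19     0.20                        0
                 16       9     0.17                        0
```

— of 172 high-quality SNPs in the simulated experiment, 97 have at
least 8 reads in both pools; their mean DI (0.24) reflects pool-sampling
noise on mostly shared polymorphism, and it falls as the depth filter
tightens because shallow, noisy sites drop out first. The
`examples/` directory has one narrative script per capability
(simulation + calling, annotation, validation comparison, read
statistics); each prints its numbers with a line on what they mean.

A thin CLI wraps the same functions:
`pooldiff simulate | count | call | sweep | annotate | validate |
report | run` (see `pooldiff --help`).

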