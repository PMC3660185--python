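"""Synthetic pooled-transcriptome data with ground truth.

The generator emulates the sampling process behind a two-pool normalized
cDNA sequencing experiment: two pools of diploid individuals (8 each by
default), per-site allele frequencies with a small minority of strongly
divergent and fixed-difference sites against a background of shared
polymorphism, unequal individual representation through per-transcript
expression weights, depth flattened by library normalization (negative
binomial with low dispersion), partial intron coverage from unspliced
transcripts, UTR overhang beyond annotated exon ends, plus sequencing
errors and ambiguous (N) calls. It emits a reference FASTA, a GTF gene
model, a two-pool pileup, a read FASTA, and truth tables for every
downstream statistic.

Reads are drawn with replacement from a pool's individuals in proportion
to their expression weights, then from the chosen individual's two allele
copies — conditionally on the genotypes, reads are therefore iid draws
from the pool's weighted allele frequency. Concentrated weights shrink the
effective number of sampled individuals, which inflates apparent
between-pool differentiation at shallow depth; this is the mechanism the
minimum-reads-per-pool filter is meant to suppress.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneModel",
    "CoverageSegment",
    "SimParams",
    "SimulatedTruth",
    "PileupRealization",
    "simulate_truth",
    "synthesize_pileup",
    "synthesize_reads",
    "write_gtf",
    "write_reference_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 1
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    utr_overhang: int = 200
    n_individuals_per_pool: int = 8
    snp_rate: float = 0.01
    p_shared: float = 0.97
    p_divergent: float = 0.025
    p_fixed: float = 0.005
    beta_alpha: float = 0.8
    beta_beta: float = 0.8
    divergent_delta: float = 0.5
    expression_weights: str = "lognormal"  # "equal" | "lognormal"
    lognormal_sigma: float = 1.0
    mean_exon_depth: float = 12.0
    depth_dispersion: float = 8.0  # NB size; large = flat normalized library
    p_intron: float = 0.2  # unspliced fraction: intron depth multiplier
    n_intergenic_segments: int = 10  # per chromosome
    intergenic_depth_factor: float = 0.5
    error_rate: float = 0.005
    n_call_rate: float = 0.002
    read_length_mean: float = 313.0
    read_length_sd: float = 100.0
    read_length_min: int = 40

    def __post_init__(self) -> None:
        probs = (self.p_shared, self.p_divergent, self.p_fixed)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("site-class proportions must sum to 1")
        for name in ("snp_rate", "error_rate", "n_call_rate", "p_intron"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_individuals_per_pool < 1:
            raise ValueError("n_individuals_per_pool must be >= 1")
        if self.expression_weights not in ("equal", "lognormal"):
            raise ValueError("expression_weights must be 'equal' or 'lognormal'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_length", "intron_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class CoverageSegment:
    """A contiguous covered interval with one depth regime."""

    chrom: str
    start: int
    end: int
    category: str        # exon | intron | utr_overhang | intergenic
    depth_factor: float  # multiplier on mean exon depth
    gene_id: str | None
    weights: np.ndarray  # (2, n_individuals) expression weights, rows sum to 1


@dataclass
class SimulatedTruth:
    params: SimParams
    reference: dict[str, str]
    genes: list[GeneModel]
    segments: list[CoverageSegment]
    variants: pd.DataFrame           # chrom,pos,ref,alt,freq_pool1,freq_pool2,true_di,category,class
    genotypes: np.ndarray            # (n_variants, 2 pools, n_ind) alt-allele dosage 0/1/2

    @property
    def truth_table(self) -> pd.DataFrame:
        return self.variants.copy()


def _lognormal_weights(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def _place_genes(params: SimParams, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = [params.n_genes // params.n_chromosomes] * params.n_chromosomes
    for i in range(params.n_genes % params.n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    for ci in range(params.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = params.utr_overhang + int(rng.integers(500, 1500))
        for _ in range(per_chrom[ci]):
            k = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
            exon_lens = rng.integers(params.exon_length[0], params.exon_length[1] + 1, size=k)
            intron_lens = rng.integers(params.intron_length[0], params.intron_length[1] + 1, size=k - 1)
            exons = []
            pos = cursor
            for j in range(k):
                exons.append((pos, pos + int(exon_lens[j])))
                pos += int(exon_lens[j])
                if j < k - 1:
                    pos += int(intron_lens[j])
            gid += 1
            if pos + params.utr_overhang > params.chromosome_length:
                raise ValueError(
                    f"gene geometry exceeds chromosome length {params.chromosome_length}; "
                    f"reduce n_genes or gene sizes"
                )
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gid:04d}",
                    transcript_id=f"TX{gid:04d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                )
            )
            cursor = pos + 2 * params.utr_overhang + int(rng.integers(1500, 4000))
    return genes


def _build_segments(
    params: SimParams, genes: list[GeneModel], rng: np.random.Generator
) -> list[CoverageSegment]:
    n_ind = params.n_individuals_per_pool

    def draw_weights() -> np.ndarray:
        if params.expression_weights == "equal":
            return np.full((2, n_ind), 1.0 / n_ind)
        return np.stack(
            [_lognormal_weights(rng, n_ind, params.lognormal_sigma) for _ in range(2)]
        )

    segments: list[CoverageSegment] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        w = draw_weights()
        start, end = gene.span
        u = params.utr_overhang
        segments.append(
            CoverageSegment(gene.chrom, start - u, start, "utr_overhang", 1.0, gene.gene_id, w)
        )
        for j, (es, ee) in enumerate(gene.exons):
            segments.append(
                CoverageSegment(gene.chrom, es, ee, "exon", 1.0, gene.gene_id, w)
            )
            if j < len(gene.exons) - 1:
                segments.append(
                    CoverageSegment(
                        gene.chrom, ee, gene.exons[j + 1][0], "intron",
                        params.p_intron, gene.gene_id, w,
                    )
                )
        segments.append(
            CoverageSegment(gene.chrom, end, end + u, "utr_overhang", 1.0, gene.gene_id, w)
        )
        occupied.setdefault(gene.chrom, []).append((start - u, end + u))

    seg_len_lo, seg_len_hi = params.exon_length
    for ci in range(params.n_chromosomes):
        chrom = f"chr{ci + 1}"
        taken = sorted(occupied.get(chrom, []))
        placed = 0
        attempts = 0
        while placed < params.n_intergenic_segments and attempts < 200:
            attempts += 1
            length = int(rng.integers(seg_len_lo, seg_len_hi + 1))
            start = int(rng.integers(0, params.chromosome_length - length))
            end = start + length
            if any(start < te and ts < end for ts, te in taken):
                continue
            segments.append(
                CoverageSegment(
                    chrom, start, end, "intergenic",
                    params.intergenic_depth_factor, None, draw_weights(),
                )
            )
            taken.append((start, end))
            taken.sort()
            placed += 1
    return segments


def simulate_truth(params: SimParams) -> SimulatedTruth:
    """Draw reference, gene models, segments, variant sites and genotypes.

    Deterministic given ``params.seed``. Variant sites fall on covered
    segments at ``snp_rate`` per bp; each is assigned a site class
    (shared / divergent / fixed), pool allele frequencies, and per-
    individual diploid genotypes drawn from those frequencies.
    """
    rng = np.random.default_rng(params.seed)
    reference = {
        f"chr{ci + 1}": "".join(
            rng.choice(_BASES, size=params.chromosome_length)
        )
        for ci in range(params.n_chromosomes)
    }
    genes = _place_genes(params, rng)
    segments = _build_segments(params, genes, rng)

    rows = []
    genos = []
    n_ind = params.n_individuals_per_pool
    class_p = np.array([params.p_shared, params.p_divergent, params.p_fixed])
    for seg in segments:
        length = seg.end - seg.start
        n_var = rng.binomial(length, params.snp_rate)
        if n_var == 0:
            continue
        offsets = np.sort(
            rng.choice(length, size=n_var, replace=False)
        )
        for off in offsets:
            pos = seg.start + int(off)
            ref = reference[seg.chrom][pos]
            alt = str(rng.choice(_BASES[_BASES != ref]))
            cls = ("shared", "divergent", "fixed")[int(rng.choice(3, p=class_p))]
            if cls == "shared":
                p = float(rng.beta(params.beta_alpha, params.beta_beta))
                p1 = p2 = p
            elif cls == "divergent":
                d = params.divergent_delta
                p1 = float(rng.uniform(0.0, 1.0 - d))
                p2 = p1 + d
                if rng.random() < 0.5:
                    p1, p2 = p2, p1
            else:
                p1, p2 = (0.0, 1.0) if rng.random() < 0.5 else (1.0, 0.0)
            true_di = abs(p1 - p2)
            g = np.stack(
                [rng.binomial(2, p1, size=n_ind), rng.binomial(2, p2, size=n_ind)]
            )
            rows.append(
                (seg.chrom, pos, ref, alt, p1, p2, true_di, seg.category, cls)
            )
            genos.append(g)
    variants = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "freq_pool1", "freq_pool2",
            "true_di", "category", "site_class",
        ],
    )
    genotypes = (
        np.stack(genos) if genos else np.empty((0, 2, n_ind), dtype=int)
    )
    return SimulatedTruth(
        params=params,
        reference=reference,
        genes=genes,
        segments=segments,
        variants=variants,
        genotypes=genotypes,
    )


@dataclass
class PileupRealization:
    """Realized per-position truth paired with the emitted pileup text."""

    depth: pd.DataFrame           # chrom,pos,category,depth_pool1,depth_pool2
    variant_counts: pd.DataFrame  # pre-error allele counts + individuals seen


def _nb_depths(
    rng: np.random.Generator, mu: float, size: int, dispersion: float
) -> np.ndarray:
    if mu <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p, size=size)


def _emit_base_symbols(
    rng: np.random.Generator, base: str, ref: str, count: int
) -> list[str]:
    if count == 0:
        return []
    strands = rng.random(count) < 0.5
    if base == ref:
        return ["." if s else "," for s in strands]
    if base == "N":
        return ["N" if s else "n" for s in strands]
    return [base if s else base.lower() for s in strands]


def synthesize_pileup(
    truth: SimulatedTruth, out: str | Path | IO[str]
) -> PileupRealization:
    """Emit a two-pool pileup for all covered positions, plus realized truth.

    Per position and pool, depth is negative binomial around the segment's
    mean; at variant positions, reads sample individuals in proportion to
    the segment's expression weights and then one of the chosen
    individual's two allele copies. Sequencing errors flip a read to a
    uniformly chosen other base; N calls replace a read's base with N.
    Intron positions that receive no read are written as reference-skip
    lines ('>'/'<' symbols only), emulating spliced-alignment gap
    positions; the gap filter must remove them.

    Returns realized depth per position (pre-error read counts) and the
    pre-error allele counts at variant positions. Deterministic given the
    truth object (a fresh stream seeded from ``params.seed`` is used).
    """
    params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    close = False
    if isinstance(out, (str, Path)):
        fh: IO[str] = open(out, "wt")
        close = True
    else:
        fh = out

    var_lookup: dict[tuple[str, int], int] = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(truth.variants["chrom"], truth.variants["pos"]))
    }
    depth_rows = []
    var_rows = []
    # segments sorted per chromosome so the pileup is coordinate-ordered
    order = sorted(truth.segments, key=lambda s: (s.chrom, s.start))
    mean_depth = params.mean_exon_depth
    for seg in order:
        length = seg.end - seg.start
        mu = seg.depth_factor * mean_depth
        depths = np.stack(
            [
                _nb_depths(rng, mu, length, params.depth_dispersion),
                _nb_depths(rng, mu, length, params.depth_dispersion),
            ]
        )
        for off in range(length):
            pos = seg.start + off
            ref = truth.reference[seg.chrom][pos]
            d = depths[:, off]
            vi = var_lookup.get((seg.chrom, pos))
            if d.sum() == 0:
                if seg.category == "intron":
                    # spliced-gap position: skips only, no aligned nucleotide
                    k = 1 + int(rng.poisson(1.5))
                    skips = "".join(">" if s else "<" for s in rng.random(k) < 0.5)
                    fh.write(
                        f"{seg.chrom}\t{pos + 1}\t{ref}\t{k}\t{skips}\t{'I' * k}"
                        f"\t0\t*\t*\n"
                    )
                continue
            pool_fields = []
            alt_counts = [0, 0]
            n_ind_seen = [0, 0]
            for pool in (0, 1):
                dp = int(d[pool])
                if dp == 0:
                    pool_fields.append("0\t*\t*")
                    continue
                if vi is not None:
                    g = truth.genotypes[vi, pool]
                    per_ind = rng.multinomial(dp, seg.weights[pool])
                    n_ind_seen[pool] = int((per_ind > 0).sum())
                    n_alt = int(rng.binomial(per_ind, g / 2.0).sum())
                else:
                    n_alt = 0
                alt_counts[pool] = n_alt
                alt = truth.variants["alt"].iat[vi] if vi is not None else None
                base_counts = {ref: dp - n_alt}
                if n_alt:
                    base_counts[alt] = base_counts.get(alt, 0) + n_alt
                # sequencing noise: N calls first, then substitution errors
                noisy: dict[str, int] = {}
                n_total = 0
                for base, cnt in base_counts.items():
                    k_n = int(rng.binomial(cnt, params.n_call_rate))
                    n_total += k_n
                    cnt -= k_n
                    k_err = int(rng.binomial(cnt, params.error_rate))
                    cnt -= k_err
                    if cnt:
                        noisy[base] = noisy.get(base, 0) + cnt
                    if k_err:
                        others = [b for b in "ACGT" if b != base]
                        spread = rng.multinomial(k_err, [1 / 3] * 3)
                        for b, kk in zip(others, spread):
                            if kk:
                                noisy[b] = noisy.get(b, 0) + int(kk)
                if n_total:
                    noisy["N"] = n_total
                symbols: list[str] = []
                for base in sorted(noisy):
                    symbols += _emit_base_symbols(rng, base, ref, noisy[base])
                rng.shuffle(symbols)
                # read-start/end markers exercise the decoder's bookkeeping
                for si in range(len(symbols)):
                    r = rng.random()
                    if r < 0.05:
                        symbols[si] = "^~" + symbols[si]
                    elif r < 0.10:
                        symbols[si] = symbols[si] + "$"
                pool_fields.append(f"{dp}\t{''.join(symbols)}\t{'I' * dp}")
            fh.write(f"{seg.chrom}\t{pos + 1}\t{ref}\t" + "\t".join(pool_fields) + "\n")
            depth_rows.append(
                (seg.chrom, pos, seg.category, int(d[0]), int(d[1]))
            )
            if vi is not None:
                var_rows.append(
                    (
                        seg.chrom, pos, ref, truth.variants["alt"].iat[vi],
                        int(d[0]), int(d[1]), alt_counts[0], alt_counts[1],
                        n_ind_seen[0], n_ind_seen[1],
                    )
                )
    if close:
        fh.close()
    depth = pd.DataFrame(
        depth_rows,
        columns=["chrom", "pos", "category", "depth_pool1", "depth_pool2"],
    )
    variant_counts = pd.DataFrame(
        var_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "depth_pool1", "depth_pool2",
            "alt_pool1", "alt_pool2", "n_individuals_pool1", "n_individuals_pool2",
        ],
    )
    return PileupRealization(depth=depth, variant_counts=variant_counts)


def synthesize_reads(
    truth: SimulatedTruth, n_reads: int, out: str | Path | IO[str]
) -> dict[str, float]:
    """Write a read FASTA with lengths ~ Normal(mean, sd) clipped at min.

    Reads are substrings of the reference (wrapping chromosomes chosen
    uniformly); returns the generator's own summary statistics so that
    downstream read accounting can be checked against it.
    """
    params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
    lengths = rng.normal(params.read_length_mean, params.read_length_sd, size=n_reads)
    lengths = np.maximum(params.read_length_min, np.rint(lengths)).astype(int)
    chroms = list(truth.reference)
    close = False
    if isinstance(out, (str, Path)):
        fh: IO[str] = open(out, "wt")
        close = True
    else:
        fh = out
    for i, length in enumerate(lengths):
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = truth.reference[chrom]
        length = min(int(length), len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        fh.write(f">read{i + 1} {chrom}:{start + 1}\n{seq[start:start + length]}\n")
    if close:
        fh.close()
    return {
        "n_reads": int(n_reads),
        "total_length": int(lengths.sum()),
        "mean_length": float(lengths.mean()) if n_reads else float("nan"),
        "min_length": int(lengths.min()) if n_reads else 0,
        "max_length": int(lengths.max()) if n_reads else 0,
    }


def write_reference_fasta(truth: SimulatedTruth, path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for chrom, seq in truth.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(truth: SimulatedTruth, path: str | Path) -> None:
    """Write exon records in Ensembl GTF dialect (1-based inclusive)."""
    with open(path, "wt") as fh:
        for gene in truth.genes:
            for start, end in gene.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{gene.transcript_id}";'
                )
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{start + 1}\t{end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
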