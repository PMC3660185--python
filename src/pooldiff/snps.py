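"""SNP calling from pooled counts and the differentiation index (DI).

A SNP is any position where at least two nucleotides are observed across
the combined pools. A *high-quality* SNP additionally requires the minor
allele (the second most common nucleotide over both pools, ties broken
alphabetically) to reach frequency >= 0.05 and at least three supporting
reads. Between-pool differentiation is measured by DI: the largest absolute
difference in nucleotide proportions between the two pools, 0 for identical
frequencies and 1 when the pools are fixed for different alleles. SNPs are
filtered by the minimum per-pool read depth, the pipeline's device against
unequal individual representation inside a pool; the threshold sweep
tabulates how SNP counts and the DI distribution respond to that filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup import BaseCounts, PooledPileupSite

__all__ = [
    "PipelineConfig",
    "SnpCall",
    "SweepRow",
    "apply_min_reads_filter",
    "call_snps",
    "call_snps_from_sites",
    "di_histogram",
    "differentiation_index",
    "flag_highly_differentiated",
    "snp_table",
    "sweep_table",
    "threshold_sweep",
]

_NUCS = ("a", "c", "g", "t")


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed thresholds of the analysis; defaults are the study's values."""

    min_maf: float = 0.05
    min_minor_reads: int = 3
    high_di_cutoff: float = 0.9
    sweep_thresholds: tuple[int, ...] = tuple(range(8, 31))
    flank_bp: int = 2000
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.min_maf < 0.5:
            raise ValueError("min_maf must lie in (0, 0.5)")
        if not 0 < self.high_di_cutoff <= 1:
            raise ValueError("high_di_cutoff must lie in (0, 1]")
        if list(self.sweep_thresholds) != sorted(set(self.sweep_thresholds)):
            raise ValueError("sweep_thresholds must be strictly increasing")


@dataclass(frozen=True)
class SnpCall:
    site: PooledPileupSite
    alleles: tuple[str, ...]          # by combined count, ties alphabetical
    minor_allele: str
    maf: float                        # combined-pool minor allele frequency
    minor_reads: int
    di: float | None                  # None when a pool has no ACGT reads
    min_pool_reads: int               # min over pools of total depth (incl. N)
    high_quality: bool


@dataclass(frozen=True)
class SweepRow:
    threshold: int
    n_snps: int
    mean_di: float | None
    n_highdiff: int


def differentiation_index(
    counts1: BaseCounts, counts2: BaseCounts
) -> float | None:
    """Largest absolute difference in nucleotide proportions between pools.

    Proportions are taken over A+C+G+T reads only; if either pool has no
    such reads the index is undefined and ``None`` is returned.
    """
    d1 = counts1.nucleotide_depth
    d2 = counts2.nucleotide_depth
    if d1 == 0 or d2 == 0:
        return None
    return max(
        abs(counts1.count(b) / d1 - counts2.count(b) / d2) for b in _NUCS
    )


def call_snps(
    site: PooledPileupSite, config: PipelineConfig = PipelineConfig()
) -> SnpCall | None:
    """Call a SNP at one site, or return ``None`` if it is monomorphic.

    Allele ranking, the minor allele, and MAF all use counts pooled across
    both pools; N calls are excluded from frequencies but counted in the
    per-pool depths used by the minimum-reads filter.
    """
    combined = site.combined
    present = [b for b in _NUCS if combined.count(b) > 0]
    if len(present) < 2:
        return None
    ranked = sorted(present, key=lambda b: (-combined.count(b), b))
    minor = ranked[1]
    nuc_total = combined.nucleotide_depth
    minor_reads = combined.count(minor)
    maf = minor_reads / nuc_total
    di = differentiation_index(site.counts[0], site.counts[1])
    return SnpCall(
        site=site,
        alleles=tuple(b.upper() for b in ranked),
        minor_allele=minor.upper(),
        maf=maf,
        minor_reads=minor_reads,
        di=di,
        min_pool_reads=min(c.total_depth for c in site.counts),
        high_quality=(maf >= config.min_maf and minor_reads >= config.min_minor_reads),
    )


def call_snps_from_sites(
    sites: Iterable[PooledPileupSite],
    config: PipelineConfig = PipelineConfig(),
    high_quality_only: bool = True,
) -> list[SnpCall]:
    calls = (call_snps(s, config) for s in sites)
    if high_quality_only:
        return [c for c in calls if c is not None and c.high_quality]
    return [c for c in calls if c is not None]


def apply_min_reads_filter(
    snps: Sequence[SnpCall], threshold: int
) -> list[SnpCall]:
    """Keep SNPs whose shallower pool has at least ``threshold`` reads."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [s for s in snps if s.min_pool_reads >= threshold]


def threshold_sweep(
    snps: Sequence[SnpCall],
    thresholds: Sequence[int] = PipelineConfig().sweep_thresholds,
    high_di_cutoff: float = 0.9,
) -> list[SweepRow]:
    """Summarize the minimum-reads filter over a range of thresholds.

    SNPs with undefined DI are excluded from every column (they cannot be
    ranked by differentiation); an empty passing set reports mean DI as
    ``None``, never 0.
    """
    if not thresholds or list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be non-empty and increasing")
    defined = [s for s in snps if s.di is not None]
    rows = []
    for t in thresholds:
        passing = apply_min_reads_filter(defined, t)
        dis = [s.di for s in passing]
        rows.append(
            SweepRow(
                threshold=t,
                n_snps=len(passing),
                mean_di=float(np.mean(dis)) if dis else None,
                n_highdiff=sum(1 for d in dis if d >= high_di_cutoff),
            )
        )
    return rows


def flag_highly_differentiated(
    snps: Sequence[SnpCall], cutoff: float = 0.9
) -> list[SnpCall]:
    """Defined-DI SNPs with DI >= cutoff (inclusive)."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    return [s for s in snps if s.di is not None and s.di >= cutoff]


def snp_table(snps: Sequence[SnpCall]) -> pd.DataFrame:
    """Report table: position, alleles, per-pool counts, DI, depth."""
    rows = []
    for s in snps:
        row: dict[str, object] = {
            "chrom": s.site.chrom,
            "pos": s.site.pos + 1,
            "ref": s.site.ref,
            "alleles": "/".join(s.alleles),
            "minor_allele": s.minor_allele,
            "maf": s.maf,
            "minor_reads": s.minor_reads,
            "di": s.di if s.di is not None else math.nan,
            "min_pool_reads": s.min_pool_reads,
            "high_quality": s.high_quality,
        }
        for p, counts in enumerate(s.site.counts, start=1):
            for b in _NUCS + ("n",):
                row[f"pool{p}_{b}"] = counts.count(b)
        rows.append(row)
    columns = [
        "chrom", "pos", "ref", "alleles", "minor_allele", "maf",
        "minor_reads", "di", "min_pool_reads", "high_quality",
    ]
    if rows:
        columns += [k for k in rows[0] if k not in columns]
    return pd.DataFrame(rows, columns=columns)


def sweep_table(rows: Sequence[SweepRow], decimals: int | None = None) -> pd.DataFrame:
    """Sweep rows as a DataFrame; ``decimals`` rounds mean DI for display."""
    df = pd.DataFrame(
        {
            "min_reads_per_pool": [r.threshold for r in rows],
            "n_snps": [r.n_snps for r in rows],
            "mean_di": [
                math.nan if r.mean_di is None else r.mean_di for r in rows
            ],
            "n_highly_differentiated": [r.n_highdiff for r in rows],
        }
    )
    if decimals is not None:
        df["mean_di"] = df["mean_di"].round(decimals)
    return df


def di_histogram(
    snps: Sequence[SnpCall], bin_width: float = 0.05
) -> pd.DataFrame:
    """DI histogram with bins [0, bin_width, ..., 1]; right edge inclusive."""
    dis = np.array([s.di for s in snps if s.di is not None])
    edges = np.round(np.arange(0, 1 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(dis, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
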