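"""Classification of covered positions against a reference gene model.

The gene model is read from an Ensembl-dialect GTF; introns are not taken
from the file but inferred per transcript as the genomic intervals between
consecutive exons. A covered position is classified as *exon* or *intron*
only when every overlapping feature agrees and belongs to a single gene;
positions overlapping features of multiple genes, or both exons and introns
of one gene (different transcripts), are *genic_ambiguous*; everything else
is *intergenic*. Intergenic positions get a distance to the nearest
gene-derived feature, with book-ended adjacency counted as 1 bp.

Strand is recorded but ignored: pileup positions are strandless. All
internal coordinates are 0-based half-open; GTF (1-based inclusive) is
converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .pileup import PooledPileupSite

__all__ = [
    "CATEGORIES",
    "FeatureIndex",
    "SiteClass",
    "build_feature_index",
    "category_statistics",
    "classify_position",
    "classify_sites",
    "distance_distribution",
    "flank_expansion_gain",
    "nearest_feature_distance",
    "unique_gene_counts",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "intron", "genic_ambiguous", "intergenic")


@dataclass(frozen=True)
class SiteClass:
    category: str
    gene_ids: frozenset[str]
    distance: int | None = None  # bp to nearest feature; intergenic only


@dataclass
class FeatureIndex:
    """Interval structures for exons, inferred introns, and gene spans."""

    trees: dict[str, IntervalTree]            # (gene, kind) payloads
    feature_starts: dict[str, np.ndarray]      # sorted, for nearest queries
    feature_ends: dict[str, np.ndarray]        # sorted ends (half-open)
    gene_spans: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    n_exons: int = 0
    n_introns: int = 0
    n_transcripts: int = 0
    excluded_chroms: frozenset[str] = frozenset()

    @property
    def genes(self) -> set[str]:
        return set(self.gene_spans)

    def chrom_has_features(self, chrom: str) -> bool:
        return chrom in self.trees and len(self.trees[chrom]) > 0


def build_feature_index(
    gtf: str | Path,
    excluded_chrom_substrings: Sequence[str] = ("_random", "chrUn"),
) -> FeatureIndex:
    """Build interval structures from a GTF's exon records.

    Per transcript with k exons, exactly k-1 introns are inferred between
    consecutive exons. Exon records missing ``gene_id`` or
    ``transcript_id`` attributes raise a load error naming them.
    ``excluded_chrom_substrings`` marks chromosomes of unplaced contigs;
    they are indexed but excluded from distance distributions.
    """
    db = gffutils.create_db(
        str(gtf),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_transcript: dict[str, list[tuple[str, int, int, str]]] = {}
    bad: list[str] = []
    for exon in db.features_of_type("exon"):
        gene = exon.attributes.get("gene_id", [None])[0]
        tx = exon.attributes.get("transcript_id", [None])[0]
        if gene is None or tx is None:
            bad.append(str(exon))
            continue
        # GTF is 1-based inclusive; gffutils keeps those coordinates
        per_transcript.setdefault(tx, []).append(
            (exon.seqid, exon.start - 1, exon.end, gene)
        )
    if bad:
        raise ValueError(
            "exon records missing gene_id/transcript_id:\n" + "\n".join(bad)
        )

    trees: dict[str, IntervalTree] = {}
    edges: dict[str, list[tuple[int, int]]] = {}
    gene_spans: dict[str, tuple[str, int, int]] = {}
    n_exons = n_introns = 0

    def _add(chrom: str, start: int, end: int, gene: str, kind: str) -> None:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, (gene, kind))
        edges.setdefault(chrom, []).append((start, end))

    for tx, exons in per_transcript.items():
        exons.sort(key=lambda e: e[1])
        for chrom, start, end, gene in exons:
            _add(chrom, start, end, gene, "exon")
            n_exons += 1
            span = gene_spans.get(gene)
            if span is None:
                gene_spans[gene] = (chrom, start, end)
            else:
                gene_spans[gene] = (span[0], min(span[1], start), max(span[2], end))
        for (chrom, _, prev_end, gene), (_, next_start, _, _) in zip(
            exons, exons[1:]
        ):
            if next_start > prev_end:
                _add(chrom, prev_end, next_start, gene, "intron")
                n_introns += 1

    starts = {
        c: np.array(sorted(s for s, _ in iv), dtype=np.int64)
        for c, iv in edges.items()
    }
    ends = {
        c: np.array(sorted(e for _, e in iv), dtype=np.int64)
        for c, iv in edges.items()
    }
    return FeatureIndex(
        trees=trees,
        feature_starts=starts,
        feature_ends=ends,
        gene_spans=gene_spans,
        n_exons=n_exons,
        n_introns=n_introns,
        n_transcripts=len(per_transcript),
        excluded_chroms=frozenset(
            c
            for c in trees
            if any(sub in c for sub in excluded_chrom_substrings)
        ),
    )


def nearest_feature_distance(
    chrom: str, pos: int, index: FeatureIndex
) -> int | None:
    """Distance in bp from an intergenic position to the nearest feature.

    Book-ended adjacency counts as 1. ``None`` when the chromosome carries
    no features at all (e.g. an unannotated chromosome).
    """
    starts = index.feature_starts.get(chrom)
    ends = index.feature_ends.get(chrom)
    if starts is None or len(starts) == 0:
        return None
    best = None
    i = int(np.searchsorted(ends, pos, side="right")) - 1
    if i >= 0:  # nearest feature ending at or left of pos (half-open end)
        best = pos - int(ends[i]) + 1
    j = int(np.searchsorted(starts, pos, side="right"))
    if j < len(starts):
        right = int(starts[j]) - pos
        best = right if best is None else min(best, right)
    return best


def classify_position(chrom: str, pos: int, index: FeatureIndex) -> SiteClass:
    """Classify a single 0-based position against the feature index."""
    tree = index.trees.get(chrom)
    if tree is None:
        logger.debug("no features for chromosome %s; treating as feature-free", chrom)
        return SiteClass("intergenic", frozenset(), None)
    hits = tree[pos]
    if not hits:
        return SiteClass(
            "intergenic", frozenset(), nearest_feature_distance(chrom, pos, index)
        )
    genes = frozenset(h.data[0] for h in hits)
    kinds = {h.data[1] for h in hits}
    if len(genes) > 1 or len(kinds) > 1:
        return SiteClass("genic_ambiguous", genes)
    return SiteClass(kinds.pop(), genes)


def classify_sites(
    sites: Iterable[PooledPileupSite], index: FeatureIndex
) -> pd.DataFrame:
    """Classify covered sites; one row per site.

    Columns: chrom, pos (0-based), total_depth, category, gene_ids
    (frozenset), distance (NaN unless intergenic with a defined distance).
    """
    rows = []
    for site in sites:
        sc = classify_position(site.chrom, site.pos, index)
        rows.append(
            (
                site.chrom,
                site.pos,
                site.total_depth,
                sc.category,
                sc.gene_ids,
                np.nan if sc.distance is None else sc.distance,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "total_depth", "category", "gene_ids", "distance"],
    )


def category_statistics(
    classified: pd.DataFrame, snp_positions: Iterable[tuple[str, int]]
) -> pd.DataFrame:
    """Per-category coverage and SNP statistics.

    Rows All / Intergenic / Genic / Exon / Intron; Genic is the union of
    exon, intron and genic-ambiguous positions, so genic bp can exceed
    exon + intron bp. SNP density is SNPs per 1,000 covered bp.
    """
    snp_set = set(snp_positions)
    is_snp = classified.apply(lambda r: (r["chrom"], r["pos"]) in snp_set, axis=1)
    genic_mask = classified["category"] != "intergenic"
    masks = {
        "All": pd.Series(True, index=classified.index),
        "Intergenic": ~genic_mask,
        "Genic": genic_mask,
        "Exon": classified["category"] == "exon",
        "Intron": classified["category"] == "intron",
    }
    rows = []
    for name, mask in masks.items():
        sub = classified[mask]
        n_bp = len(sub)
        n_snps = int(is_snp[mask].sum())
        rows.append(
            {
                "feature": name,
                "n_bp": n_bp,
                "mean_depth": float(sub["total_depth"].mean()) if n_bp else np.nan,
                "min_depth": int(sub["total_depth"].min()) if n_bp else 0,
                "max_depth": int(sub["total_depth"].max()) if n_bp else 0,
                "n_snps": n_snps,
                "snp_density": 1000 * n_snps / n_bp if n_bp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def unique_gene_counts(classified: pd.DataFrame, mode: str = "exclude_multi") -> int:
    """Number of distinct genes reached by covered positions.

    ``exclude_multi`` counts genes reached through single-gene (exon or
    intron) positions only; ``include_multi`` also credits every gene of
    multi-gene ambiguous positions. include_multi >= exclude_multi always.
    """
    if mode not in ("exclude_multi", "include_multi"):
        raise ValueError(f"unknown mode {mode!r}")
    genes: set[str] = set()
    for category, gene_ids in zip(classified["category"], classified["gene_ids"]):
        if category == "intergenic":
            continue
        if len(gene_ids) > 1 and mode == "exclude_multi":
            continue
        # single-gene ambiguous positions (mixed exon/intron) are genic
        # overlap with exactly one gene and count in both modes
        genes.update(gene_ids)
    return len(genes)


def flank_expansion_gain(
    classified: pd.DataFrame, index: FeatureIndex, flank_bp: int = 2000
) -> int:
    """Genes gained by expanding gene spans by ``flank_bp`` on both sides.

    Counts genes with no covered position inside their annotated span but
    at least one within the expanded span — the transcriptome signal that
    annotated gene ends underestimate true (UTR-bearing) transcript ends.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in classified.groupby("chrom")
    }
    gained = 0
    for chrom, start, end in index.gene_spans.values():
        positions = pos_by_chrom.get(chrom)
        if positions is None:
            continue
        inside = np.searchsorted(positions, end, "left") - np.searchsorted(
            positions, start, "left"
        )
        if inside > 0:
            continue
        expanded = np.searchsorted(
            positions, end + flank_bp, "left"
        ) - np.searchsorted(positions, max(0, start - flank_bp), "left")
        if expanded > 0:
            gained += 1
    return gained


def distance_distribution(
    classified: pd.DataFrame,
    index: FeatureIndex,
    bins: Sequence[int] | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Summary and histogram of intergenic nearest-feature distances.

    Positions on excluded chromosomes (unplaced contigs) and positions with
    undefined distance (feature-free chromosomes) do not enter. Returns a
    summary dict (n, mean, median, min, max) and a histogram DataFrame
    whose counts sum to n.
    """
    mask = (
        (classified["category"] == "intergenic")
        & classified["distance"].notna()
        & ~classified["chrom"].isin(index.excluded_chroms)
    )
    distances = classified.loc[mask, "distance"].to_numpy(dtype=float)
    if len(distances) == 0:
        return (
            {"n": 0, "mean": np.nan, "median": np.nan, "min": np.nan, "max": np.nan},
            pd.DataFrame(columns=["bin_left", "bin_right", "count"]),
        )
    summary = {
        "n": int(len(distances)),
        "mean": float(distances.mean()),
        "median": float(np.median(distances)),
        "min": float(distances.min()),
        "max": float(distances.max()),
    }
    if bins is None:
        edges = np.histogram_bin_edges(distances, bins=20)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(distances, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return summary, hist
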