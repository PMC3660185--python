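"""Read-set accounting, per-chromosome correlation, and orchestration.

`read_statistics` streams FASTA/FASTQ once and keeps only counters, so
arbitrarily large read sets fit in constant memory. `aggregate_runs`
combines sequencing runs the only correct way — summed reads and summed
length, with the combined mean length-weighted (never a mean of means).
`run_pipeline` wires the whole analysis together: simulate (or load)
inputs, count bases per position, call SNPs, sweep the depth filter,
annotate, and write every table plus a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from . import annotate as ann
from . import pileup as pio
from . import simulate as sim
from . import snps as sd

__all__ = [
    "ReadSetStats",
    "aggregate_runs",
    "bundled_run_statistics",
    "chromosome_read_correlation",
    "read_statistics",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadSetStats:
    n_reads: int
    total_length: int
    mean_length: float | None
    min_length: int | None
    max_length: int | None

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "ReadSetStats":
        n = total = 0
        lo = hi = None
        for length in lengths:
            n += 1
            total += length
            lo = length if lo is None else min(lo, length)
            hi = length if hi is None else max(hi, length)
        return cls(n, total, total / n if n else None, lo, hi)


def read_statistics(path: str | Path, fmt: str | None = None) -> ReadSetStats:
    """Streaming length statistics for a FASTA/FASTQ file."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {
            "fa": "fasta", "fasta": "fasta", "fna": "fasta",
            "fq": "fastq", "fastq": "fastq",
        }.get(suffix, "fasta")
    return ReadSetStats.from_lengths(
        len(rec.seq) for rec in SeqIO.parse(str(path), fmt)
    )


def aggregate_runs(runs: Sequence[ReadSetStats]) -> ReadSetStats:
    """Combine runs: counts and lengths sum; mean is length-weighted."""
    if not runs:
        raise ValueError("need at least one run")
    n = sum(r.n_reads for r in runs)
    total = sum(r.total_length for r in runs)
    mins = [r.min_length for r in runs if r.min_length is not None]
    maxs = [r.max_length for r in runs if r.max_length is not None]
    return ReadSetStats(
        n_reads=n,
        total_length=total,
        mean_length=total / n if n else None,
        min_length=min(mins) if mins else None,
        max_length=max(maxs) if maxs else None,
    )


def bundled_run_statistics() -> pd.DataFrame:
    """Packaged per-run read statistics (raw and filtered sets)."""
    with resources.files("pooldiff.data").joinpath("read_runs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def run_stats_from_table(df: pd.DataFrame, read_set: str) -> list[ReadSetStats]:
    sub = df[df["read_set"] == read_set]
    return [
        ReadSetStats(
            n_reads=int(r.n_reads),
            total_length=int(r.total_length_bp),
            mean_length=float(r.total_length_bp) / int(r.n_reads),
            min_length=int(r.min_length_bp),
            max_length=int(r.max_length_bp),
        )
        for r in sub.itertuples()
    ]


def chromosome_read_correlation(
    read_counts: Sequence[int], chrom_lengths: Sequence[int]
) -> float | None:
    """Pearson correlation of per-chromosome read count with length."""
    if len(read_counts) != len(chrom_lengths):
        raise ValueError("read_counts and chrom_lengths must align")
    if len(read_counts) < 3:
        raise ValueError("need at least 3 chromosomes")
    x = np.asarray(read_counts, dtype=float)
    y = np.asarray(chrom_lengths, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    out_dir: str | Path,
    sim_params: sim.SimParams | None = None,
    pileup_path: str | Path | None = None,
    gtf_path: str | Path | None = None,
    config: sd.PipelineConfig = sd.PipelineConfig(),
) -> dict[str, object]:
    """Run the full analysis and write all tables plus a manifest.

    Either ``sim_params`` (generate inputs) or both ``pileup_path`` and
    ``gtf_path`` (use existing files) must be given. Outputs: site table,
    SNP table, highly-differentiated table, sweep table, DI histogram,
    per-category statistics, distance summary/histogram, and
    ``manifest.json`` with parameters, record counts, stage timings and
    output digests. Deterministic given inputs and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
        "counts": {},
    }

    def stage(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)  # type: ignore[index]
        logger.info("stage %s finished in %.2fs", name, manifest["stages"][name])  # type: ignore[index]
        return result

    if sim_params is not None:
        manifest["parameters"]["simulation"] = dataclasses.asdict(sim_params)  # type: ignore[index]

        def _simulate():
            truth = sim.simulate_truth(sim_params)
            sim.write_reference_fasta(truth, out / "reference.fa")
            sim.write_gtf(truth, out / "genes.gtf")
            realization = sim.synthesize_pileup(truth, out / "pools.pileup")
            truth.truth_table.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
            realization.depth.to_csv(out / "truth_depth.tsv", sep="\t", index=False)
            return truth

        stage("simulate", _simulate)
        pileup_path = out / "pools.pileup"
        gtf_path = out / "genes.gtf"
    if pileup_path is None or gtf_path is None:
        raise ValueError("need sim_params, or pileup_path and gtf_path")
    for path in (pileup_path, gtf_path):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    sites = stage(
        "count", lambda: list(pio.parse_pileup(pileup_path, n_pools=2))
    )
    pio.write_site_table(sites, out / "sites.tsv")
    manifest["counts"]["sites"] = len(sites)  # type: ignore[index]

    snps = stage(
        "call", lambda: sd.call_snps_from_sites(sites, config)
    )
    sd.snp_table(snps).to_csv(out / "snps.tsv", sep="\t", index=False)
    manifest["counts"]["high_quality_snps"] = len(snps)  # type: ignore[index]

    def _sweep():
        rows = sd.threshold_sweep(
            snps, config.sweep_thresholds, config.high_di_cutoff
        )
        sd.sweep_table(rows).to_csv(out / "sweep.tsv", sep="\t", index=False)
        sd.di_histogram(snps).to_csv(out / "di_histogram.tsv", sep="\t", index=False)
        high = sd.flag_highly_differentiated(snps, config.high_di_cutoff)
        sd.snp_table(high).to_csv(
            out / "highly_differentiated.tsv", sep="\t", index=False
        )
        return rows, high

    sweep_rows, high = stage("sweep", _sweep)
    manifest["counts"]["highly_differentiated"] = len(high)  # type: ignore[index]

    def _annotate():
        index = ann.build_feature_index(gtf_path)
        classified = ann.classify_sites(sites, index)
        snp_pos = [(s.site.chrom, s.site.pos) for s in snps]
        cat = ann.category_statistics(classified, snp_pos)
        cat.to_csv(out / "category_stats.tsv", sep="\t", index=False)
        summary, hist = ann.distance_distribution(classified, index)
        hist.to_csv(out / "distance_histogram.tsv", sep="\t", index=False)
        with open(out / "distance_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        classified.drop(columns=["gene_ids"]).to_csv(
            out / "classified_sites.tsv", sep="\t", index=False
        )
        return index, classified, cat, summary

    index, classified, cat_stats, dist_summary = stage("annotate", _annotate)
    manifest["counts"]["unique_genes_exclude_multi"] = ann.unique_gene_counts(  # type: ignore[index]
        classified, "exclude_multi"
    )
    manifest["counts"]["unique_genes_include_multi"] = ann.unique_gene_counts(  # type: ignore[index]
        classified, "include_multi"
    )
    manifest["counts"]["flank_expansion_gain"] = ann.flank_expansion_gain(  # type: ignore[index]
        classified, index, config.flank_bp
    )

    for path in sorted(out.glob("*.tsv")) + [out / "distance_summary.json"]:
        manifest["outputs"][path.name] = _digest(path)  # type: ignore[index]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
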