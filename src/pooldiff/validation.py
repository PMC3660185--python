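"""Genotype-based differentiation and comparison with pooled estimates.

Candidate SNPs from pooled sequencing are re-genotyped in independent
individuals (Sanger-style); each group's allele counts come from diploid
calls (two observations per non-missing cell) and differentiation between
groups uses the same largest-absolute-proportion-difference index as the
pooled pipeline. Comparing the pooled DI against the genotype-based DI as
a function of per-pool read depth quantifies how depth filtering controls
the pooled estimate's bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup import BaseCounts
from .snps import differentiation_index

__all__ = [
    "RegressionResult",
    "bundled_validation_records",
    "count_validated_differentiated",
    "depth_delta_regression",
    "di_from_genotypes",
    "load_genotype_table",
]

MISSING = {"", ".", "NA", "nan", "--", None}


def load_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV: individual, population, one column per SNP.

    Cells are diploid calls like ``AG`` (or ``A/G``); missing cells are
    empty, ``.``, ``NA`` or ``--``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype table must have columns {sorted(required)}")
    return df


def _allele_counts(calls: Sequence[str | float]) -> BaseCounts:
    counts = {"a": 0, "c": 0, "g": 0, "t": 0, "n": 0}
    for call in calls:
        if call is None or (isinstance(call, float) and np.isnan(call)):
            continue
        text = str(call).replace("/", "").replace("|", "").strip()
        if text in MISSING or text.upper() in {"NA", "--"}:
            continue
        if len(text) != 2:
            raise ValueError(f"diploid call must have two alleles, got {call!r}")
        for allele in text.upper():
            if allele == "N":
                counts["n"] += 1
            elif allele in "ACGT":
                counts[allele.lower()] += 1
            else:
                raise ValueError(f"unknown allele {allele!r} in call {call!r}")
    return BaseCounts(**counts)


def di_from_genotypes(
    table: pd.DataFrame, group_a: str, group_b: str, snp: str
) -> float | None:
    """DI between two population groups at one SNP column.

    Allele counts per group come from the diploid calls (missing cells are
    simply dropped). Returns ``None`` when a group has no genotyped
    individual for the SNP — the estimate is undefined, not zero.
    """
    if snp not in table.columns:
        raise KeyError(f"SNP column {snp!r} not in genotype table")
    counts = {}
    for group in (group_a, group_b):
        rows = table.loc[table["population"] == group, snp]
        counts[group] = _allele_counts(rows.tolist())
    return differentiation_index(counts[group_a], counts[group_b])


@dataclass(frozen=True)
class RegressionResult:
    r: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    n: int


def depth_delta_regression(records: pd.DataFrame) -> RegressionResult:
    """Correlate per-pool read depth with the pooled-vs-validation DI gap.

    ``records`` needs columns ``min_reads_pool``, ``di_454`` and
    ``di_validation``; delta = di_454 - di_validation. Returns the Pearson
    r with its two-sided t-distribution p-value (n-2 df) and the
    least-squares line of delta on depth. Zero variance in either variable
    flags the correlation as undefined.
    """
    sub = records.dropna(subset=["min_reads_pool", "di_454", "di_validation"])
    if len(sub) < 3:
        raise ValueError("need at least 3 records with defined delta")
    x = sub["min_reads_pool"].to_numpy(dtype=float)
    delta = (sub["di_454"] - sub["di_validation"]).to_numpy(dtype=float)
    # tolerance absorbs float noise in nominally constant deltas
    if np.ptp(x) < 1e-12 or np.ptp(delta) < 1e-12:
        return RegressionResult(None, None, None, None, len(sub))
    lr = stats.linregress(x, delta)
    return RegressionResult(
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=len(sub),
    )


def count_validated_differentiated(
    records: pd.DataFrame, cutoff: float = 0.6, column: str = "di_validation"
) -> int:
    """Records whose validation DI is strictly greater than ``cutoff``."""
    values = records[column].dropna()
    return int((values > cutoff).sum())


def bundled_validation_records() -> pd.DataFrame:
    """The packaged validation-comparison table.

    Columns: gene, position, min_reads_pool, di_454, di_validation (the
    within-country subspecies contrast; 0.00 where the genotyped samples
    showed no frequency difference) and di_validation_alt (the second,
    cross-country contrast where one was typed).
    """
    with resources.files("pooldiff.data").joinpath("validation_records.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
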