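"""Decoding of samtools-mpileup text into per-pool nucleotide counts.

The pileup base column encodes, per aligned read, either a reference match
('.' forward / ',' reverse), a substitution (ACGT, case gives strand), an
ambiguous call (N/n), or bookkeeping symbols: '^q' read start (the next
character is a mapping quality), '$' read end, '+k<seq>'/'-k<seq>' indels,
'*' a deleted base, and '<'/'>' reference skips from spliced alignments.

This pipeline counts nucleotides only: indels are skipped entirely, deleted
bases and reference skips contribute to no depth figure, and N calls are
counted separately (they enter total depth but never allele frequencies).
Positions spanned exclusively by spliced-alignment gaps carry no aligned
nucleotide at all and are removed before any downstream statistic.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "BaseCounts",
    "PooledPileupSite",
    "PileupError",
    "decode_base_string",
    "parse_pileup",
    "read_site_table",
    "write_site_table",
]

_NUCS = ("a", "c", "g", "t")


class PileupError(ValueError):
    """Malformed pileup text (bad base-column grammar or line structure)."""


@dataclass(frozen=True)
class BaseCounts:
    """Read counts for one position in one pool.

    ``n`` counts ambiguous (N) calls; they contribute to :attr:`total_depth`
    but never to :attr:`nucleotide_depth`, which is the denominator of every
    allele-frequency computation.
    """

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t, self.n) < 0:
            raise ValueError("base counts must be non-negative")

    @property
    def nucleotide_depth(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def total_depth(self) -> int:
        return self.nucleotide_depth + self.n

    def as_dict(self) -> dict[str, int]:
        return {"a": self.a, "c": self.c, "g": self.g, "t": self.t, "n": self.n}

    def count(self, base: str) -> int:
        return getattr(self, base.lower())


@dataclass(frozen=True)
class PooledPileupSite:
    """One genomic position with per-pool base counts.

    ``pos`` is 0-based (half-open convention throughout the package); the
    1-based pileup coordinate is converted on input and restored on output.
    """

    chrom: str
    pos: int
    ref: str
    counts: tuple[BaseCounts, ...]

    @property
    def total_depth(self) -> int:
        return sum(c.total_depth for c in self.counts)

    @property
    def combined(self) -> BaseCounts:
        return BaseCounts(
            a=sum(c.a for c in self.counts),
            c=sum(c.c for c in self.counts),
            g=sum(c.g for c in self.counts),
            t=sum(c.t for c in self.counts),
            n=sum(c.n for c in self.counts),
        )


def decode_base_string(bases: str, ref: str) -> BaseCounts:
    """Decode one pileup base column into nucleotide counts.

    '.'/',' increment the reference base; letters increment their own base
    case-insensitively; N/n count as ambiguous. '^' consumes the following
    quality character, '$' is consumed, indel specifications are consumed
    whole, and '*', '<', '>' consume one symbol each without contributing
    to any count.

    Raises :class:`PileupError` on a truncated '^' or malformed indel.
    """
    ref = ref.upper()
    counts = {"a": 0, "c": 0, "g": 0, "t": 0, "n": 0}
    i = 0
    length = len(bases)
    while i < length:
        ch = bases[i]
        if ch in ".,":
            if ref in "ACGT":
                counts[ref.lower()] += 1
            else:  # reference N: a match carries no nucleotide information
                counts["n"] += 1
            i += 1
        elif ch in "ACGTacgt":
            counts[ch.lower()] += 1
            i += 1
        elif ch in "Nn":
            counts["n"] += 1
            i += 1
        elif ch == "^":
            if i + 1 >= length:
                raise PileupError(
                    f"truncated '^' read-start at offset {i} in column {bases!r}"
                )
            i += 2  # '^' plus mapping-quality character
        elif ch == "$":
            i += 1
        elif ch in "+-":
            j = i + 1
            while j < length and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupError(
                    f"indel without length at offset {i} in column {bases!r}"
                )
            k = int(bases[i + 1 : j])
            if j + k > length:
                raise PileupError(
                    f"indel sequence truncated at offset {i} in column {bases!r}"
                )
            i = j + k
        elif ch in "*<>":
            i += 1
        else:
            raise PileupError(
                f"unexpected symbol {ch!r} at offset {i} in column {bases!r}"
            )
    return BaseCounts(**counts)


def _only_skips(bases: str) -> bool:
    """True when a base column encodes no aligned nucleotide at all."""
    i = 0
    length = len(bases)
    while i < length:
        ch = bases[i]
        if ch in "<>*$":
            i += 1
        elif ch == "^":
            i += 2
        elif ch in "+-":
            j = i + 1
            while j < length and bases[j].isdigit():
                j += 1
            i = j + int(bases[i + 1 : j] or 0)
        else:
            return False
    return True


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def parse_pileup(
    source: str | Path | IO[str] | Iterable[str],
    n_pools: int = 2,
    drop_gap_positions: bool = True,
) -> Iterator[PooledPileupSite]:
    """Stream sites from multi-sample pileup text.

    Each line is ``chrom pos ref`` followed by ``depth bases quals`` per
    pool. With ``drop_gap_positions`` (the default), positions whose decoded
    total depth across pools is zero — typically spliced-alignment gaps
    where every symbol is a reference skip — are removed.

    The per-pool declared depth is reconciled against the decoded counts;
    disagreement beyond what skipped/deleted symbols explain raises a
    warning (declared depth may legitimately exceed the reconstructed total
    because '*' and '<'/'>' contribute to no count here).
    """
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if hasattr(source, "read") or isinstance(source, (str, Path)):
        stream: Iterable[str] = _open_text(source)  # type: ignore[arg-type]
    else:
        stream = source
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space-separated toy input
            fields = line.split()
        expected = 3 + 3 * n_pools
        if len(fields) != expected:
            raise PileupError(
                f"line {lineno}: expected {expected} columns for {n_pools} "
                f"pools, found {len(fields)}"
            )
        chrom, pos_str, ref = fields[0], fields[1], fields[2]
        pools: list[BaseCounts] = []
        all_skips = True
        for p in range(n_pools):
            declared = int(fields[3 + 3 * p])
            bases = fields[4 + 3 * p]
            if declared == 0 and bases in ("*", ""):
                pools.append(BaseCounts())
                continue
            try:
                counts = decode_base_string(bases, ref)
            except PileupError as exc:
                raise PileupError(f"line {lineno}, pool {p + 1}: {exc}") from exc
            if counts.total_depth > declared:
                warnings.warn(
                    f"line {lineno}, pool {p + 1}: decoded depth "
                    f"{counts.total_depth} exceeds declared depth {declared}",
                    stacklevel=2,
                )
            pools.append(counts)
            if not _only_skips(bases):
                all_skips = False
        site = PooledPileupSite(
            chrom=chrom, pos=int(pos_str) - 1, ref=ref.upper(), counts=tuple(pools)
        )
        if drop_gap_positions and (site.total_depth == 0 or all_skips):
            continue
        yield site


_TABLE_COLUMNS = ("chrom", "pos", "ref")
_POOL_FIELDS = ("a", "c", "g", "t", "n")


def write_site_table(
    sites: Iterable[PooledPileupSite], path: str | Path, n_pools: int = 2
) -> int:
    """Write sites as TSV (1-based positions, per-pool count columns).

    Returns the number of rows written. The header names every column, e.g.
    ``pool1_a``; the file round-trips losslessly through
    :func:`read_site_table`.
    """
    header = list(_TABLE_COLUMNS)
    for p in range(1, n_pools + 1):
        header += [f"pool{p}_{f}" for f in _POOL_FIELDS]
    rows = 0
    with open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for site in sites:
            cells = [site.chrom, str(site.pos + 1), site.ref]
            for counts in site.counts:
                cells += [str(counts.count(f)) for f in _POOL_FIELDS]
            fh.write("\t".join(cells) + "\n")
            rows += 1
    return rows


def read_site_table(path: str | Path) -> Iterator[PooledPileupSite]:
    """Read a TSV written by :func:`write_site_table`."""
    with open(path, "rt") as fh:
        header_line = fh.readline()
        if not header_line:
            raise PileupError(f"{path}: empty site table (missing header)")
        header = header_line.rstrip("\n").split("\t")
        if header[:3] != list(_TABLE_COLUMNS) or (len(header) - 3) % 5 != 0:
            raise PileupError(f"{path}: unrecognized site-table header")
        n_pools = (len(header) - 3) // 5
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise PileupError(f"{path}:{lineno}: column count mismatch")
            pools = []
            for p in range(n_pools):
                base = 3 + 5 * p
                pools.append(
                    BaseCounts(*(int(cells[base + k]) for k in range(5)))
                )
            yield PooledPileupSite(
                chrom=cells[0], pos=int(cells[1]) - 1, ref=cells[2],
                counts=tuple(pools),
            )
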