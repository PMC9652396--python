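"""Genome model and interval arithmetic.

All coordinates in this package are 0-based, half-open (BED convention):
an interval covers base pairs ``start .. end-1``. Inputs using 1-based,
fully-closed coordinates must be converted by the caller; nothing here
shifts coordinates silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "CoordinateError",
    "merge_overlapping",
    "filter_by_overlap",
    "read_bed",
    "write_bed",
]


class CoordinateError(ValueError):
    """An interval falls outside its chromosome or violates start < end."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on ``chrom``.

    Carrier type for cCREs (open-chromatin elements), heterochromatin
    domains, called clusters, TSS anchors and blacklist entries.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.id or '?'}: "
                f"{self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r} for {self.id!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeLayout:
    """Ordered set of chromosomes with lengths; the coordinate universe.

    Stands in for a reference assembly: every interval handled by the
    pipeline must lie on one of these chromosomes.
    """

    def __init__(self, chromosomes: Sequence[tuple[str, int]]):
        names = [c for c, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths: dict[str, int] = dict(chromosomes)
        self.names: tuple[str, ...] = tuple(names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for name in self.names:
            yield name, self._lengths[name]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def validate(self, interval: GenomicInterval) -> None:
        """Raise CoordinateError naming the record if it leaves the genome."""
        if interval.chrom not in self._lengths:
            raise CoordinateError(
                f"interval {interval.id or '?'} on unknown chromosome {interval.chrom!r}"
            )
        if interval.end > self._lengths[interval.chrom]:
            raise CoordinateError(
                f"interval {interval.id or '?'} "
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self._lengths[interval.chrom]}"
            )


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_overlapping(
    intervals: Sequence[GenomicInterval],
    genome: GenomeLayout | None = None,
) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals into a disjoint sorted set.

    Touching intervals (one's end == other's start) are merged, so the
    output is a minimal disjoint cover of the input union, sorted by
    (chrom, start) with chromosome order taken from ``genome`` when given,
    lexicographic otherwise.
    """
    if genome is not None:
        for iv in intervals:
            genome.validate(iv)
    grouped = _by_chrom(intervals)
    chrom_order = (
        [c for c in genome.names if c in grouped] if genome is not None
        else sorted(grouped)
    )
    merged: list[GenomicInterval] = []
    for chrom in chrom_order:
        ivs = sorted(grouped[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or touch
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def filter_by_overlap(
    intervals: Sequence[GenomicInterval],
    excluded_regions: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition ``intervals`` by >= 1 bp overlap with any excluded region.

    Returns ``(kept, removed)``; input order is preserved within each
    list. Used both for dropping elements in high-signal repeat families
    and for blacklist removal.
    """
    excl = _by_chrom(merge_overlapping(excluded_regions)) if excluded_regions else {}
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in excl.items():
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])
    kept: list[GenomicInterval] = []
    removed: list[GenomicInterval] = []
    for iv in intervals:
        hit = False
        if iv.chrom in starts:
            # rightmost excluded region starting before iv.end
            j = int(np.searchsorted(starts[iv.chrom], iv.end, side="left")) - 1
            hit = j >= 0 and ends[iv.chrom][j] > iv.start
        (removed if hit else kept).append(iv)
    return kept, removed


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, no header) into intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name, strand, score))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t"
                    f"{iv.score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
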