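"""Pseudo-bulk sample keys, count matrices, fragment files and counting.

A pseudo-bulk sample aggregates all fragments from nuclei sharing a cell
type, an age group and a biological replicate. Count matrices are
features x samples with non-negative integer entries (raw mode) or
columns normalised to one million (CPM mode).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval

__all__ = [
    "SampleKey",
    "CountMatrix",
    "FragmentRecord",
    "FragmentParseError",
    "read_fragments",
    "write_fragments",
    "count_fragments_in_intervals",
    "jaccard_index",
]

MAX_INSERT_SIZE = 2000  # proper ATAC read pairs only


class FragmentParseError(ValueError):
    """A malformed line in a fragments file, reported with its line number."""


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FragmentParseError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.end - self.start >= MAX_INSERT_SIZE:
            raise FragmentParseError(
                f"fragment {self.chrom}:{self.start}-{self.end}: insert size "
                f"{self.end - self.start} >= {MAX_INSERT_SIZE}"
            )


@dataclass(frozen=True)
class SampleKey:
    """Identity and bookkeeping of one pseudo-bulk sample."""

    cell_type: str
    age_months: int
    replicate: int
    n_cells: int = 1
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"sample {self.label}: n_cells must be positive")

    @property
    def label(self) -> str:
        return f"{self.cell_type}.{self.age_months}.{self.replicate}"


class CountMatrix:
    """Features x pseudo-bulk samples count matrix with sample metadata."""

    def __init__(
        self,
        feature_ids: Sequence[str],
        samples: Sequence[SampleKey],
        counts: np.ndarray,
        mode: str = "raw",
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(feature_ids), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(samples)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("feature ids are not unique")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if mode not in ("raw", "CPM"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        self.feature_ids = list(feature_ids)
        self.samples = list(samples)
        self.counts = counts
        self.mode = mode

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=float)

    def column(self, label: str) -> np.ndarray:
        labels = [s.label for s in self.samples]
        return self.counts[:, labels.index(label)]

    def with_library_sizes_from_counts(self) -> "CountMatrix":
        """Rewrite each SampleKey.library_size as its actual column sum."""
        sums = self.counts.sum(axis=0)
        samples = [replace(s, library_size=int(t)) for s, t in zip(self.samples, sums)]
        return CountMatrix(self.feature_ids, samples, self.counts, self.mode)

    def subset_samples(self, mask: Sequence[bool]) -> "CountMatrix":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        return CountMatrix(
            self.feature_ids,
            [self.samples[i] for i in idx],
            self.counts[:, idx],
            self.mode,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.feature_ids, name="feature"),
            columns=[s.label for s in self.samples],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, metadata: Mapping[str, SampleKey] | None = None,
                 mode: str = "raw") -> "CountMatrix":
        """Read a TSV with feature-id row names and ``celltype.age.rep`` headers.

        ``metadata`` maps column labels to full SampleKeys; without it,
        n_cells defaults to 1 and library_size to the column sum.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples = []
        for label in df.columns:
            if metadata is not None and label in metadata:
                samples.append(metadata[label])
            else:
                cell_type, age, rep = label.rsplit(".", 2)
                samples.append(
                    SampleKey(cell_type, int(age), int(rep),
                              library_size=int(df[label].sum()))
                )
        return cls(list(df.index), samples, df.to_numpy(), mode=mode)


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime so identical content gives identical bytes
            import io
            raw = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(raw) if "t" in mode else raw
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> Iterator[FragmentRecord]:
    """Stream a 4-column fragments file (chrom, start, end, barcode)."""
    with _open_maybe_gzip(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FragmentParseError(f"{path}:{ln}: expected 4 columns")
            try:
                rec = FragmentRecord(parts[0], int(parts[1]), int(parts[2]), parts[3])
            except (ValueError, FragmentParseError) as exc:
                raise FragmentParseError(f"{path}:{ln}: {exc}") from None
            yield rec


def write_fragments(path, fragments: Iterable[FragmentRecord]) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\n")


def count_fragments_in_intervals(
    fragments: Iterable[FragmentRecord],
    intervals: Sequence[GenomicInterval],
    barcode_to_sample: Mapping[str, SampleKey],
) -> tuple[CountMatrix, int]:
    """Count fragments per (interval, pseudo-bulk sample) by >= 1 bp overlap.

    Intervals must be disjoint and pre-merged. A fragment overlapping k
    intervals increments each of the k cells once; barcodes absent from
    the mapping are skipped, and their total is returned alongside the
    matrix (real fragment files contain filtered nuclei).

    Returns ``(matrix, n_unmapped_barcode_fragments)``.
    """
    samples: list[SampleKey] = []
    sample_index: dict[SampleKey, int] = {}
    for key in barcode_to_sample.values():
        if key not in sample_index:
            sample_index[key] = len(samples)
            samples.append(key)

    by_chrom_starts: dict[str, np.ndarray] = {}
    by_chrom_ends: dict[str, np.ndarray] = {}
    by_chrom_rows: dict[str, np.ndarray] = {}
    chrom_groups: dict[str, list[int]] = {}
    for row, iv in enumerate(intervals):
        chrom_groups.setdefault(iv.chrom, []).append(row)
    for chrom, rows in chrom_groups.items():
        rows_sorted = sorted(rows, key=lambda r: intervals[r].start)
        by_chrom_starts[chrom] = np.array([intervals[r].start for r in rows_sorted])
        by_chrom_ends[chrom] = np.array([intervals[r].end for r in rows_sorted])
        by_chrom_rows[chrom] = np.array(rows_sorted)

    counts = np.zeros((len(intervals), len(samples)), dtype=np.int64)
    unmapped = 0
    for frag in fragments:
        key = barcode_to_sample.get(frag.barcode)
        if key is None:
            unmapped += 1
            continue
        col = sample_index[key]
        starts = by_chrom_starts.get(frag.chrom)
        if starts is None:
            continue
        ends = by_chrom_ends[frag.chrom]
        # disjoint sorted intervals: overlaps form a contiguous run
        lo = int(np.searchsorted(ends, frag.start, side="right"))
        hi = int(np.searchsorted(starts, frag.end, side="left"))
        if hi > lo:
            counts[by_chrom_rows[frag.chrom][lo:hi], col] += 1

    feature_ids = [iv.id or f"iv{n}" for n, iv in enumerate(intervals)]
    mat = CountMatrix(feature_ids, samples, counts).with_library_sizes_from_counts()
    return mat, unmapped


def jaccard_index(set_a: set, set_b: set) -> float:
    """Intersection-over-union of two feature-id sets; 0 when both empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union
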