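"""Quality control: TSS enrichment, nucleus filtering, read down-sampling.

The TSS enrichment score is the standard ATAC-seq library-quality
metric: Tn5 insertion events (cut sites corrected by +4 bp on the plus
strand and -5 bp on the minus strand) are aggregated around every TSS,
normalised to the distal-flank mean and smoothed; the score is the
maximum of the smoothed profile. A flat insertion landscape scores ~1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .counts import FragmentRecord
from .genome import GenomicInterval

__all__ = [
    "TssProfile",
    "NucleusStats",
    "tss_enrichment",
    "insertion_events",
    "per_barcode_stats",
    "filter_nuclei",
    "downsample_sample",
]

FLANK = 2000
FLANK_NORM_MIN = 1900  # normalisation uses positions +-1900..+-2000
SMOOTH_BP = 11


@dataclass
class TssProfile:
    positions: np.ndarray    # -2000..+2000, strand-corrected
    raw: np.ndarray          # insertion events per bp
    normalized: np.ndarray   # raw / flank mean
    smoothed: np.ndarray     # 11-bp centred moving average
    score: float             # max of the smoothed profile


@dataclass(frozen=True)
class NucleusStats:
    barcode: str
    n_fragments: int
    tss_enrichment: float


def insertion_events(fragments: Iterable[FragmentRecord]) -> dict[str, np.ndarray]:
    """Tn5-corrected cut sites per chromosome, two per fragment.

    The fragment start is treated as the plus-strand cut (shift +4) and
    the last covered base (end - 1) as the minus-strand cut (shift -5).
    """
    per_chrom: dict[str, list[int]] = {}
    for f in fragments:
        lst = per_chrom.setdefault(f.chrom, [])
        lst.append(f.start + 4)
        lst.append(f.end - 1 - 5)
    return {c: np.sort(np.asarray(v, dtype=np.int64))
            for c, v in per_chrom.items()}


def _smooth(values: np.ndarray, width: int = SMOOTH_BP) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def profile_from_raw(raw: np.ndarray, flank: int = FLANK) -> TssProfile:
    """Normalise-then-smooth evaluation of an aggregated insertion profile."""
    raw = np.asarray(raw, dtype=float)
    if raw.sum() == 0:
        raise ValueError("no insertions")
    positions = np.arange(-flank, flank + 1)
    flank_mask = np.abs(positions) >= FLANK_NORM_MIN
    flank_mean = raw[flank_mask].mean()
    if flank_mean == 0:
        flank_mean = raw.sum() / (len(raw) * 50.0)
        warnings.warn("zero flank signal; flank mean floored", stacklevel=2)
    normalized = raw / flank_mean
    smoothed = _smooth(normalized)
    return TssProfile(positions, raw, normalized, smoothed,
                      float(smoothed.max()))


def tss_enrichment(
    fragments: Iterable[FragmentRecord] | dict[str, np.ndarray],
    tss_list: Sequence[GenomicInterval],
    flank: int = FLANK,
) -> TssProfile:
    """Aggregate TSS-centred insertion profile and its enrichment score.

    ``fragments`` may be fragment records or pre-computed per-chromosome
    insertion arrays. Minus-strand TSS profiles are reversed before
    aggregation so position +x always means x bp downstream of the TSS.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    events = (fragments if isinstance(fragments, dict)
              else insertion_events(fragments))
    width = 2 * flank + 1
    raw = np.zeros(width)
    for t in tss_list:
        arr = events.get(t.chrom)
        if arr is None or len(arr) == 0:
            continue
        pos = t.start
        lo = np.searchsorted(arr, pos - flank, side="left")
        hi = np.searchsorted(arr, pos + flank, side="right")
        rel = arr[lo:hi] - pos
        if t.strand == "-":
            rel = -rel
        raw += np.bincount(rel + flank, minlength=width)
    return profile_from_raw(raw, flank)


def per_barcode_stats(
    fragments: Iterable[FragmentRecord],
    tss_list: Sequence[GenomicInterval],
) -> list[NucleusStats]:
    """Per-nucleus fragment count and TSS enrichment, each nucleus from
    its own fragments alone."""
    by_barcode: dict[str, list[FragmentRecord]] = {}
    for f in fragments:
        by_barcode.setdefault(f.barcode, []).append(f)
    out = []
    for barcode in sorted(by_barcode):
        frags = by_barcode[barcode]
        try:
            score = tss_enrichment(frags, tss_list).score
        except ValueError:
            score = 0.0
        out.append(NucleusStats(barcode, len(frags), score))
    return out


def filter_nuclei(
    stats: Sequence[NucleusStats],
    min_fragments: int = 500,
    min_tss: float = 10.0,
) -> list[str]:
    """Barcodes passing both the fragment-count and TSS-enrichment cutoffs.

    The reference thresholds are 500 fragments and TSS enrichment 10
    (7 for low-complexity tissues such as heart and leg muscle).
    """
    if min_fragments <= 0 or min_tss <= 0:
        raise ValueError("thresholds must be positive")
    return [s.barcode for s in stats
            if s.n_fragments >= min_fragments and s.tss_enrichment >= min_tss]


def downsample_sample(
    counts: np.ndarray,
    target: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray | None:
    """Down-sample one sample's feature counts to exactly ``target`` reads.

    Sampling is without replacement (multivariate hypergeometric over
    features), matching subsampling of real reads. Samples with fewer
    than ``target`` reads are removed: the function returns ``None``.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < target:
        return None
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.multivariate_hypergeometric(counts.astype(np.int64), target,
                                           method="marginals")
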