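"""Gene-cCRE linking by weighted Pearson correlation and concordance.

Pseudo-bulk replicates are merged into one data point per (cell type,
age group); for every gene and every cCRE whose midpoint lies within a
window (500 kb by default) of the gene's TSS, the weighted Pearson
correlation coefficient (WPCC) between gene CPM and cCRE CPM is
computed across data points, weighting each point by its cell count to
damp outliers from rare cell types. P-values use a t approximation with
the Kish effective sample size n_eff = (sum w)^2 / sum w^2; the
reference workflow does not state how its p-values were derived from
the weighted correlation, so this choice is flagged here and in the
package docs. BH correction is applied across ALL tested pairs
(stricter than per-gene correction); significant links require adjusted
p below the cutoff AND a positive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .counts import CountMatrix, SampleKey
from .differential import DifferentialRecord, bh_adjust
from .genome import GenomicInterval

__all__ = [
    "LinkRecord",
    "ConcordanceResult",
    "weighted_pearson",
    "merge_replicates",
    "link_gene_ccres",
    "concordance_test",
]


@dataclass(frozen=True)
class LinkRecord:
    gene_id: str
    ccre_id: str
    distance: int
    wpcc: float
    p_value: float
    p_adjusted: float
    n_points: int
    n_eff: float
    significant: bool = False
    flagged: bool = False    # zero-variance pair; wpcc undefined


@dataclass(frozen=True)
class ConcordanceResult:
    up_log2fc: np.ndarray     # gene log2FCs linked to age-up cCREs
    down_log2fc: np.ndarray
    statistic: float
    p_value: float
    n_concordant: int
    flagged: bool = False


def weighted_pearson(x, y, w) -> tuple[float, float]:
    """Weighted Pearson correlation and a two-sided t-approximation p-value.

    Invariant to rescaling of the weights. Zero weighted variance in
    either variable yields (nan, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)) or len(x) < 3:
        raise ValueError("need equal-length x, y, w with >= 3 points")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        return float("nan"), 1.0
    r = float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))
    n_eff = wsum**2 / (w**2).sum()
    if n_eff <= 2 or abs(r) >= 1.0:
        p = 0.0 if (abs(r) >= 1.0 and n_eff > 2) else 1.0
        return r, p
    t = r * np.sqrt((n_eff - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=n_eff - 2))
    return r, p


def kish_n_eff(w) -> float:
    w = np.asarray(w, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def merge_replicates(matrix: CountMatrix) -> CountMatrix:
    """Sum replicate columns into one pseudo-bulk per (cell type, age).

    Cell counts add up; the merged column keeps replicate number 0.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault((s.cell_type, s.age_months), []).append(j)
    keys = sorted(groups)
    counts = np.column_stack(
        [matrix.counts[:, groups[k]].sum(axis=1) for k in keys])
    samples = []
    for (ct, age), cols in ((k, groups[k]) for k in keys):
        n_cells = sum(matrix.samples[j].n_cells for j in cols)
        samples.append(SampleKey(ct, age, 0, n_cells,
                                 int(counts[:, keys.index((ct, age))].sum())))
    return CountMatrix(matrix.feature_ids, samples, counts, mode=matrix.mode)


def link_gene_ccres(
    atac_cpm: CountMatrix,
    rna_cpm: CountMatrix,
    ccres: Sequence[GenomicInterval],
    tss_list: Sequence[GenomicInterval],
    window: int = 500_000,
    alpha: float = 0.05,
) -> list[LinkRecord]:
    """WPCC linking of every gene to every cCRE within ``window`` of its TSS.

    Both matrices must be CPM over identical merged (cell type, age)
    data points; weights are the per-point cell counts. Returns all
    tested pairs, with ``significant`` set where BH-adjusted p < alpha
    and the correlation is positive.
    """
    keys_a = [(s.cell_type, s.age_months) for s in atac_cpm.samples]
    keys_r = [(s.cell_type, s.age_months) for s in rna_cpm.samples]
    if keys_a != keys_r:
        diff = set(keys_a) ^ set(keys_r)
        raise ValueError(f"sample keys differ between matrices: {sorted(diff)}")
    w = np.array([s.n_cells for s in atac_cpm.samples], dtype=float)

    ccre_mid = {}
    for iv in ccres:
        ccre_mid.setdefault(iv.chrom, []).append((iv.midpoint, iv.id))
    mids = {c: np.array([m for m, _ in sorted(v)]) for c, v in ccre_mid.items()}
    ids = {c: [i for _, i in sorted(v)] for c, v in ccre_mid.items()}

    atac_rows = {fid: k for k, fid in enumerate(atac_cpm.feature_ids)}
    rna_rows = {fid: k for k, fid in enumerate(rna_cpm.feature_ids)}

    records: list[LinkRecord] = []
    for t in tss_list:
        gid = t.id
        if gid not in rna_rows or t.chrom not in mids:
            continue
        pos = t.start
        m = mids[t.chrom]
        lo = int(np.searchsorted(m, pos - window, side="left"))
        hi = int(np.searchsorted(m, pos + window, side="right"))
        y = rna_cpm.counts[rna_rows[gid]].astype(float)
        for j in range(lo, hi):
            cid = ids[t.chrom][j]
            if cid not in atac_rows:
                continue
            x = atac_cpm.counts[atac_rows[cid]].astype(float)
            r, p = weighted_pearson(x, y, w)
            records.append(LinkRecord(
                gene_id=gid, ccre_id=cid, distance=abs(int(m[j]) - pos),
                wpcc=r, p_value=p, p_adjusted=1.0, n_points=len(w),
                n_eff=kish_n_eff(w), flagged=bool(np.isnan(r))))
    if not records:
        return records
    padj = bh_adjust(np.array([rec.p_value for rec in records]))
    return [replace(rec, p_adjusted=float(q),
                    significant=bool(q < alpha and not rec.flagged
                                     and rec.wpcc > 0))
            for rec, q in zip(records, padj)]


def concordance_test(
    links: Sequence[LinkRecord],
    age_up: set[str],
    age_down: set[str],
    gene_records: Sequence[DifferentialRecord],
) -> ConcordanceResult:
    """Do genes linked to age-up cCREs gain expression relative to genes
    linked to age-down cCREs?

    Collects the RNA log2 fold change (old over young) of genes linked
    to age-up and to age-down cCREs (a gene may appear in both groups
    through different elements) and compares the two distributions with
    a two-sided Wilcoxon rank-sum test (normal approximation, tie
    corrected). Also counts concordant pairs: up-linked genes with
    positive log2FC plus down-linked genes with negative log2FC.
    """
    lfc = {rec.feature_id: rec.log2fc for rec in gene_records}
    up_vals, down_vals = [], []
    n_conc = 0
    for link in links:
        if not link.significant or link.gene_id not in lfc:
            continue
        v = lfc[link.gene_id]
        if link.ccre_id in age_up:
            up_vals.append(v)
            n_conc += v > 0
        elif link.ccre_id in age_down:
            down_vals.append(v)
            n_conc += v < 0
    up = np.asarray(up_vals, dtype=float)
    down = np.asarray(down_vals, dtype=float)
    if len(up) == 0 or len(down) == 0:
        return ConcordanceResult(up, down, float("nan"), float("nan"),
                                 n_conc, flagged=True)
    res = stats.mannwhitneyu(up, down, alternative="two-sided",
                             method="asymptotic")
    return ConcordanceResult(up, down, float(res.statistic),
                             float(res.pvalue), n_conc)
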