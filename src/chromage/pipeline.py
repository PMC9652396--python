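"""End-to-end driver: simulate, QC, test, link, cluster, and score domains.

``run_all(seed, outdir)`` executes the whole pipeline on the synthetic
study and writes plain-text outputs (BED/TSV/JSON/YAML). Everything is
deterministic given the seed: two runs produce byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from . import clusters as cl
from . import domains as dm
from . import linking as lk
from . import qc
from .counts import CountMatrix, jaccard_index, write_fragments
from .differential import (annotate_directions, cpm_normalize,
                           classify_age_ccres, estimate_dispersions, nb_lrt)
from .genome import write_bed
from .simulate import (EXN, Annotation, SimConfig, SimCounts,
                       generate_annotation, generate_counts,
                       generate_fragments)

__all__ = ["run_all", "differential_by_cell_type"]


def differential_by_cell_type(
    matrix: CountMatrix,
    ages: tuple = (3, 18),
    alpha: float = 0.01,
    use_adjusted: bool = False,
) -> dict[str, list]:
    """Old-vs-young NB LRT per cell type; directions annotated at alpha."""
    out = {}
    for ct in sorted({s.cell_type for s in matrix.samples}):
        mask = [s.cell_type == ct and s.age_months in ages
                for s in matrix.samples]
        sub = matrix.subset_samples(mask)
        labels = [s.age_months for s in sub.samples]
        disp = estimate_dispersions(sub, labels)
        recs = nb_lrt(sub, labels, disp, group_order=ages)
        out[ct] = annotate_directions(recs, alpha=alpha,
                                      use_adjusted=use_adjusted)
    return out


def _records_frame(records_by_ct: dict[str, list]) -> pd.DataFrame:
    rows = []
    for ct, recs in records_by_ct.items():
        for r in recs:
            rows.append({"cell_type": ct, "feature_id": r.feature_id,
                         "log2fc": r.log2fc, "lrt": r.lrt_stat,
                         "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                         "direction": r.direction})
    return pd.DataFrame(rows)


def run_all(seed: int, outdir: str, config: SimConfig | None = None,
            n_perm: int = 1000, verbose: bool = True) -> dict:
    """Run the full synthetic study; returns the summary dictionary."""
    cfg = config if config is not None else SimConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = replace(config, seed=seed)
    os.makedirs(outdir, exist_ok=True)
    log = print if verbose else (lambda *a, **k: None)

    # ------------------------------------------------------------- simulate
    ann = generate_annotation(cfg)
    sim = generate_counts(ann, cfg)
    frags, barcode_map = generate_fragments(ann, cfg)
    cfg.to_yaml(f"{outdir}/config.yaml")
    write_bed(f"{outdir}/ccres.bed", ann.ccres)
    write_bed(f"{outdir}/tss.bed", ann.genes)
    write_bed(f"{outdir}/domains.bed", ann.domains)
    ann.truth.write(f"{outdir}/truth")
    sim.atac.write_tsv(f"{outdir}/counts_atac.tsv")
    sim.rna.write_tsv(f"{outdir}/counts_rna.tsv")
    sim.k9_domains.write_tsv(f"{outdir}/counts_k9_domains.tsv")
    write_fragments(f"{outdir}/fragments.tsv.gz", frags)
    log(f"simulated {len(ann.ccres)} cCREs, {len(ann.genes)} genes, "
        f"{len(ann.domains)} domains, {len(frags)} fragments")

    # ------------------------------------------------------------------ QC
    stats = qc.per_barcode_stats(frags, ann.genes)
    kept = qc.filter_nuclei(stats)
    pd.DataFrame([{"barcode": s.barcode, "n_fragments": s.n_fragments,
                   "tss_enrichment": s.tss_enrichment} for s in stats]).to_csv(
        f"{outdir}/barcode_stats.tsv", sep="\t", index=False)
    with open(f"{outdir}/kept_barcodes.txt", "w") as fh:
        fh.write("\n".join(kept) + "\n")
    pooled_tss = qc.tss_enrichment(frags, ann.genes).score
    log(f"QC: kept {len(kept)}/{len(stats)} barcodes; "
        f"pooled TSS enrichment {pooled_tss:.2f}")

    # fair-comparison down-sampling of the ATAC pseudo-bulks
    ds_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    ds_cols, ds_keep = [], []
    for j, s in enumerate(sim.atac.samples):
        out = qc.downsample_sample(sim.atac.counts[:, j], 1_000_000, ds_rng)
        if out is not None:
            ds_cols.append(out)
            ds_keep.append(j)
    ds = CountMatrix(sim.atac.feature_ids,
                     [sim.atac.samples[j] for j in ds_keep],
                     np.column_stack(ds_cols)).with_library_sizes_from_counts()
    ds.write_tsv(f"{outdir}/counts_atac_downsampled_1M.tsv")

    # ---------------------------------------------------------- differential
    atac_records = differential_by_cell_type(sim.atac)
    _records_frame(atac_records).to_csv(f"{outdir}/differential_atac.tsv",
                                        sep="\t", index=False)
    up_sets, down_sets = {}, {}
    for ct, recs in atac_records.items():
        up_sets[ct], down_sets[ct] = classify_age_ccres(recs, alpha=0.01)
        log(f"differential[{ct}]: {len(up_sets[ct])} age-up, "
            f"{len(down_sets[ct])} age-down cCREs (p<0.01)")

    cts = sorted(atac_records)
    jac = pd.DataFrame(
        [[jaccard_index(up_sets[a] | down_sets[a], up_sets[b] | down_sets[b])
          for b in cts] for a in cts], index=cts, columns=cts)
    jac.to_csv(f"{outdir}/jaccard_age_ccres.tsv", sep="\t")

    # --------------------------------------------------------------- clusters
    ccre_by_id = ann.ccre_by_id()
    all_calls = []
    for ct in cts:
        for direction in ("up", "down"):
            track = cl.bin_differential_counts(
                atac_records[ct], ccre_by_id, ann.layout,
                cell_type=ct, direction=direction)
            smoothed = cl.gaussian_smooth(track)
            calls = cl.call_ccre_clusters(
                smoothed, track, ann.ccres, n_perm=n_perm,
                seed=int(np.random.SeedSequence(seed, spawn_key=(8,))
                         .generate_state(1)[0] % 2**31))
            all_calls.extend(calls)
    write_bed(f"{outdir}/clusters.bed",
              [replace(c.interval, score=float(c.peak_score))
               for c in all_calls])
    log(f"clusters: {len(all_calls)} calls "
        f"({sum(c.direction == 'up' for c in all_calls)} up)")

    # ---------------------------------------------------------------- domains
    domain_calls = dm.call_broad_domains(sim.k9_positions, ann.layout)
    write_bed(f"{outdir}/domains_called.bed",
              [d.interval for d in domain_calls])
    log(f"domain caller: {len(domain_calls)} broad domains "
        f"(true: {len(ann.domains)})")

    # tri-modal per-domain differential on the true domain grid
    atac_dom = _aggregate_over_domains(sim.atac, ann, "ccres")
    rna_dom = _aggregate_over_domains(sim.rna, ann, "genes")
    dom_records = dm.domain_differential({
        "H3K9me3": sim.k9_domains, "ATAC": atac_dom, "RNA": rna_dom})
    pd.DataFrame([asdict(r) for r in dom_records]).to_csv(
        f"{outdir}/domain_differential.tsv", sep="\t", index=False)

    decaying_ids = ann.truth.domains.loc[
        ann.truth.domains["decaying"], "domain_id"].tolist()
    frip_records, frip_p = dm.fraction_reads_in_domains(
        sim.cell_domain_reads[sim.cell_domain_reads["cell_type"] == EXN],
        decaying_ids)
    pd.DataFrame([asdict(r) for r in frip_records]).to_csv(
        f"{outdir}/frip_exn.tsv", sep="\t", index=False)
    log(f"FRiP (ExN, decaying domains): rank-sum p = {frip_p:.3g}")

    # ------------------------------------------------------------ enrichment
    fisher = dm.fisher_overlap_enrichment(
        atac_records[EXN], ccre_by_id, ann.domains)
    up_clusters = [c.interval for c in all_calls
                   if c.direction == "up" and c.cell_type == EXN]
    overlap = dm.cluster_domain_overlap_enrichment(
        [d.interval for d in domain_calls], up_clusters, ann.layout,
        n_shuffles=n_perm,
        seed=int(np.random.SeedSequence(seed, spawn_key=(9,))
                 .generate_state(1)[0] % 2**31))
    log(f"top-1% Fisher: OR={fisher.odds_ratio:.2f} p={fisher.fisher_p:.3g}; "
        f"domain-cluster overlap: observed={overlap.observed_fraction:.3f} "
        f"fold={overlap.fold_enrichment:.2f} p={overlap.shuffle_p:.3g}")

    # --------------------------------------------------------------- linking
    atac_cpm = cpm_normalize(lk.merge_replicates(sim.atac))
    rna_cpm = cpm_normalize(lk.merge_replicates(sim.rna))
    links = lk.link_gene_ccres(atac_cpm, rna_cpm, ann.ccres, ann.genes)
    sig = [l for l in links if l.significant]
    pd.DataFrame([asdict(l) for l in sig]).to_csv(
        f"{outdir}/links.tsv", sep="\t", index=False)

    rna_records = differential_by_cell_type(sim.rna, alpha=0.1,
                                            use_adjusted=True)
    conc = _pooled_concordance(links, atac_records, rna_records)
    log(f"linking: {len(sig)}/{len(links)} significant pairs; "
        f"concordance p = {conc.p_value:.3g} "
        f"({conc.n_concordant} concordant pairs)")

    summary = {
        "seed": seed,
        "n_ccres": len(ann.ccres),
        "n_genes": len(ann.genes),
        "pooled_tss_enrichment": round(pooled_tss, 4),
        "n_barcodes_kept": len(kept),
        "n_barcodes_total": len(stats),
        "age_up": {ct: len(up_sets[ct]) for ct in cts},
        "age_down": {ct: len(down_sets[ct]) for ct in cts},
        "n_clusters_called": len(all_calls),
        "n_domains_called": len(domain_calls),
        "frip_ranksum_p": frip_p,
        "fisher_top1pct_or": fisher.odds_ratio,
        "fisher_top1pct_p": fisher.fisher_p,
        "domain_cluster_observed": overlap.observed_fraction,
        "domain_cluster_fold": overlap.fold_enrichment,
        "domain_cluster_shuffle_p": overlap.shuffle_p,
        "n_links_significant": len(sig),
        "n_links_tested": len(links),
        "concordance_p": conc.p_value,
        "concordance_n": conc.n_concordant,
    }
    with open(f"{outdir}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _aggregate_over_domains(matrix: CountMatrix, ann: Annotation,
                            which: str) -> CountMatrix:
    """Sum feature counts over each domain (features assigned by midpoint)."""
    feats = ann.ccres if which == "ccres" else ann.genes
    rows = {iv.id: i for i, iv in enumerate(feats)}
    agg = np.zeros((len(ann.domains), len(matrix.samples)), dtype=np.int64)
    for di, dom in enumerate(ann.domains):
        for iv in feats:
            if iv.chrom == dom.chrom and dom.start <= iv.midpoint < dom.end:
                agg[di] += matrix.counts[rows[iv.id]].astype(np.int64)
    # ensure positive library sizes even for empty domains
    out = CountMatrix([d.id for d in ann.domains], matrix.samples, agg)
    return out


def _pooled_concordance(links, atac_records_by_ct, rna_records_by_ct):
    """Concordance pooled over cell types: per cell type, gene log2FCs of
    genes linked to that cell type's age-up vs age-down cCREs."""
    from .linking import ConcordanceResult
    up_all, down_all = [], []
    n_conc = 0
    for ct, recs in atac_records_by_ct.items():
        up, down = classify_age_ccres(recs, alpha=0.01)
        lfc = {r.feature_id: r.log2fc for r in rna_records_by_ct[ct]}
        for link in links:
            if not link.significant or link.gene_id not in lfc:
                continue
            v = lfc[link.gene_id]
            if link.ccre_id in up:
                up_all.append(v)
                n_conc += v > 0
            elif link.ccre_id in down:
                down_all.append(v)
                n_conc += v < 0
    up = np.asarray(up_all)
    down = np.asarray(down_all)
    if len(up) == 0 or len(down) == 0:
        return ConcordanceResult(up, down, float("nan"), float("nan"),
                                 n_conc, flagged=True)
    from scipy import stats as sps
    res = sps.mannwhitneyu(up, down, alternative="two-sided",
                           method="asymptotic")
    return ConcordanceResult(up, down, float(res.statistic),
                             float(res.pvalue), int(n_conc))
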