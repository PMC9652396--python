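"""Synthetic genomes, annotations, fragments and counts with planted truth.

The generator emulates the statistical structure of a multi-tissue
single-nucleus chromatin-accessibility aging study at desk scale:

* pseudo-bulk samples over cell types x age groups (3, 10, 18 months)
  x biological replicates, with negative-binomial counts;
* a minority of cCREs whose accessibility changes monotonically with
  age (a fixed multiplicative fold per age step) in specific cell types;
* megabase-scale clusters of age-up cCREs planted inside decaying
  heterochromatin (H3K9me3) domains of one excitatory-neuron-like cell
  type;
* RNA counts for a subset of genes coupled to the accessibility of
  their linked cCREs through a shared latent activity, calibrated to a
  target correlation;
* H3K9me3 domain signal that decays with age in the ExN-like cell type
  only, with per-cell read-to-domain assignments;
* a barcoded fragments file with a TSS-centred insertion pile-up for
  quality-control testing.

Every quantity with a planted effect is recorded in truth tables so the
whole downstream pipeline can be scored for recovery. One seed drives
everything; stage sub-streams are derived from it by fixed spawn keys so
each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix, FragmentRecord, SampleKey
from .genome import GenomeLayout, GenomicInterval

__all__ = [
    "SimConfig",
    "TruthTables",
    "Annotation",
    "SimCounts",
    "generate_annotation",
    "generate_counts",
    "generate_fragments",
]

EXN = "ExN"  # the excitatory-neuron-like cell type carrying planted decay


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 1
    chromosomes: tuple = (("chr1", 20_000_000), ("chr2", 20_000_000))
    n_cell_types: int = 3
    ages: tuple = (3, 10, 18)
    n_replicates: int = 2
    n_ccres: int = 4000
    n_genes: int = 600
    n_domains: int = 10
    domain_size_range: tuple = (500_000, 1_500_000)
    domain_min_gap: int = 2_000_000   # keeps distinct domains resolvable
    fraction_decaying_domains: float = 0.4
    # per-cCRE baseline abundance ~ lognormal(mu_log, sigma_log), relative
    ccre_mu_log: float = 0.0
    ccre_sigma_log: float = 1.0
    # per-(cCRE, cell type) accessibility factor ~ lognormal(0, celltype_sigma)
    celltype_sigma: float = 0.5
    dispersion: float = 0.1          # NB dispersion of cCRE / gene counts
    domain_dispersion: float = 0.005  # NB dispersion of Mb-scale domain counts
    age_fold: float = 1.5            # multiplicative fold per age step
    fraction_age_up: float = 0.05    # of non-cluster cCREs
    fraction_age_down: float = 0.05
    n_clusters: int = 3
    ccres_per_cluster: int = 100
    cluster_span: int = 1_000_000
    library_size: int = 2_000_000    # ATAC reads per pseudo-bulk sample
    rna_library_size: int = 2_000_000
    k9_library_size: int = 500_000
    cells_per_sample: int = 500
    rna_link_rho: float = 0.8        # target gene-cCRE correlation
    n_linked_genes: int = 200
    domain_decay: float = 0.3        # delta: 18-month factor = 1 - delta
    # fragments-file generation (QC stage)
    tss_fold: float = 15.0
    tss_plateau_halfwidth: int = 100
    frags_per_barcode_median: float = 2500.0
    frags_per_barcode_sigma: float = 0.35
    lowq_fraction: float = 0.1
    # per-cell H3K9me3 depth for the FRiP statistic
    k9_reads_per_cell: float = 2000.0
    k9_in_domain_fraction: float = 0.6
    k9_domain_enrichment: float = 8.0  # domain/background density of K9 signal
    k9_background_per_5kb: float = 20.0

    def __post_init__(self) -> None:
        for name in ("fraction_decaying_domains", "fraction_age_up",
                     "fraction_age_down", "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_clusters > 0:
            n_decay = int(round(self.n_domains * self.fraction_decaying_domains))
            if self.n_clusters > n_decay:
                raise ValueError(
                    f"{self.n_clusters} clusters cannot be planted in "
                    f"{n_decay} decaying domains")
        if self.cluster_span > self.domain_size_range[1]:
            raise ValueError("cluster_span exceeds maximal domain size")

    @property
    def cell_types(self) -> list[str]:
        extra = [f"ct{i}" for i in range(4, self.n_cell_types + 1)]
        return ([EXN, "Oligo", "Micro"][: self.n_cell_types] + extra)[
            : self.n_cell_types]

    @property
    def age_step(self) -> dict[int, int]:
        return {age: i for i, age in enumerate(sorted(self.ages))}

    def sample_keys(self) -> list[tuple[str, int, int]]:
        return [(ct, age, rep)
                for ct in self.cell_types
                for age in sorted(self.ages)
                for rep in range(1, self.n_replicates + 1)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class TruthTables:
    ccres: pd.DataFrame      # id, direction, cell_type, fold, cluster_id
    genes: pd.DataFrame      # gene_id, linked_ccres, rho
    domains: pd.DataFrame    # domain_id, chrom, start, end, decaying, delta
    clusters: pd.DataFrame   # cluster_id, chrom, start, end, domain_id, cell_type, n_ccres

    def write(self, directory) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        for name in ("ccres", "genes", "domains", "clusters"):
            getattr(self, name).to_csv(
                f"{directory}/{name}.tsv", sep="\t", index=False)


@dataclass
class Annotation:
    layout: GenomeLayout
    ccres: list[GenomicInterval]
    genes: list[GenomicInterval]     # one 1-bp TSS interval per gene, stranded
    domains: list[GenomicInterval]
    truth: TruthTables

    def ccre_by_id(self) -> dict[str, GenomicInterval]:
        return {iv.id: iv for iv in self.ccres}


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _place_disjoint(rng: np.random.Generator, sizes: Sequence[int],
                    segment: tuple[int, int],
                    min_gap: int = 0) -> list[tuple[int, int]]:
    """Place intervals of the given sizes disjointly and uniformly in a segment.

    Uniform over arrangements: random order of sizes, slack distributed
    as sorted uniform gaps. ``min_gap`` enforces a minimum separation
    between neighbouring intervals.
    """
    lo, hi = segment
    sizes = list(sizes)
    pad = min_gap * max(len(sizes) - 1, 0)
    free = (hi - lo) - sum(sizes) - pad
    if free < 0:
        raise ValueError(
            f"cannot pack {sum(sizes)} bp of features (+{pad} bp gaps) "
            f"into a {hi - lo} bp segment")
    order = rng.permutation(len(sizes))
    cuts = np.sort(rng.uniform(0, free, size=len(sizes)))
    out: list[tuple[int, int] | None] = [None] * len(sizes)
    pos = lo
    prev_cut = 0.0
    for slot, idx in enumerate(order):
        pos += int(cuts[slot] - prev_cut)
        prev_cut = cuts[slot]
        out[idx] = (pos, pos + sizes[idx])
        pos += sizes[idx] + (min_gap if slot < len(sizes) - 1 else 0)
    return out  # type: ignore[return-value]


def generate_annotation(config: SimConfig) -> Annotation:
    """Genome, domains, planted clusters, cCREs, genes/TSSs and truth tables.

    Deterministic given ``config.seed``: running twice yields identical
    objects and identical files on disk.
    """
    layout = GenomeLayout(list(config.chromosomes))
    chrom_names = list(layout.names)

    # --- heterochromatin domains: disjoint, round-robin over chromosomes ---
    rng = _rng(config.seed, 0)
    dom_sizes = rng.integers(config.domain_size_range[0],
                             config.domain_size_range[1] + 1,
                             size=config.n_domains)
    n_decay = int(round(config.n_domains * config.fraction_decaying_domains))
    decaying_idx = sorted(rng.choice(config.n_domains, size=n_decay,
                                     replace=False).tolist())
    host_idx = (sorted(rng.choice(decaying_idx, size=config.n_clusters,
                                  replace=False).tolist())
                if config.n_clusters > 0 else [])
    # cluster-hosting domains must be able to contain a full-span cluster
    for i in host_idx:
        dom_sizes[i] = max(int(dom_sizes[i]),
                           min(config.cluster_span + 100_000,
                               config.domain_size_range[1]))
    dom_chroms = [chrom_names[i % len(chrom_names)]
                  for i in range(config.n_domains)]
    placements: dict[str, list[int]] = {}
    for i, c in enumerate(dom_chroms):
        placements.setdefault(c, []).append(i)
    domains: list[GenomicInterval | None] = [None] * config.n_domains
    for chrom, idxs in placements.items():
        spans = _place_disjoint(rng, [int(dom_sizes[i]) for i in idxs],
                                (0, layout.length(chrom)),
                                min_gap=config.domain_min_gap)
        for i, (s, e) in zip(idxs, spans):
            domains[i] = GenomicInterval(chrom, s, e, f"domain_{i:02d}")

    # --- planted clusters inside distinct decaying domains ---
    clusters: list[GenomicInterval] = []
    for k, di in enumerate(host_idx):
        dom = domains[di]
        span = min(config.cluster_span, len(dom))
        start = dom.start + int(rng.integers(0, len(dom) - span + 1))
        clusters.append(GenomicInterval(dom.chrom, start, start + span,
                                        f"cluster_{k}"))

    # --- cCREs: cluster members first, then the rest in the free genome ---
    ccre_sizes_rng = lambda n: rng.integers(200, 1001, size=n)
    placed: list[tuple[str, int, int, str | None]] = []  # chrom,start,end,cluster
    for cl in clusters:
        sizes = ccre_sizes_rng(config.ccres_per_cluster)
        for s, e in _place_disjoint(rng, sizes.tolist(), (cl.start, cl.end)):
            placed.append((cl.chrom, s, e, cl.id))
    n_rest = config.n_ccres - len(placed)
    if n_rest < 0:
        raise ValueError("planted cluster cCREs exceed n_ccres")
    # free segments = chromosomes minus cluster spans
    free_segments: list[tuple[str, int, int]] = []
    for chrom, length in layout:
        occupied = sorted((c.start, c.end) for c in clusters if c.chrom == chrom)
        pos = 0
        for s, e in occupied:
            if s > pos:
                free_segments.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            free_segments.append((chrom, pos, length))
    seg_len = np.array([e - s for _, s, e in free_segments], dtype=float)
    alloc = rng.multinomial(n_rest, seg_len / seg_len.sum())
    for (chrom, s, e), k in zip(free_segments, alloc):
        if k == 0:
            continue
        sizes = ccre_sizes_rng(int(k))
        for cs, ce in _place_disjoint(rng, sizes.tolist(), (s, e)):
            placed.append((chrom, cs, ce, None))
    placed.sort(key=lambda t: (chrom_names.index(t[0]), t[1]))
    ccres = [GenomicInterval(c, s, e, f"ccre_{i:05d}")
             for i, (c, s, e, _) in enumerate(placed)]
    cluster_of = {f"ccre_{i:05d}": cl for i, (_, _, _, cl) in enumerate(placed)}

    # --- planted age effects ---
    cell_types = config.cell_types
    direction = {iv.id: "null" for iv in ccres}
    affected_ct = {iv.id: "" for iv in ccres}
    non_cluster = [iv.id for iv in ccres if cluster_of[iv.id] is None]
    n_up = int(round(config.fraction_age_up * len(non_cluster)))
    n_down = int(round(config.fraction_age_down * len(non_cluster)))
    pick = rng.choice(len(non_cluster), size=n_up + n_down, replace=False)
    for j in pick[:n_up]:
        direction[non_cluster[j]] = "up"
    for j in pick[n_up:]:
        direction[non_cluster[j]] = "down"
    for cid in non_cluster:
        if direction[cid] != "null":
            affected_ct[cid] = cell_types[int(rng.integers(len(cell_types)))]
    for iv in ccres:  # cluster members: age-up in the ExN-like type
        if cluster_of[iv.id] is not None:
            direction[iv.id] = "up"
            affected_ct[iv.id] = EXN

    # --- genes: linked genes anchored near cCREs, the rest uniform ---
    up_pool = [c for c in non_cluster if direction[c] == "up"]
    down_pool = [c for c in non_cluster if direction[c] == "down"]
    null_pool = [c for c in non_cluster if direction[c] == "null"]
    n_link = min(config.n_linked_genes, config.n_genes)
    n_anchor_up = min(len(up_pool), n_link // 4)
    n_anchor_down = min(len(down_pool), n_link // 4)
    anchors = (
        [up_pool[i] for i in rng.choice(len(up_pool), n_anchor_up, replace=False)]
        + [down_pool[i] for i in rng.choice(len(down_pool), n_anchor_down,
                                            replace=False)]
        + [null_pool[i] for i in rng.choice(
            len(null_pool), n_link - n_anchor_up - n_anchor_down,
            replace=False)]
    )
    by_id = {iv.id: iv for iv in ccres}
    mids = {chrom: np.array([iv.midpoint for iv in ccres if iv.chrom == chrom])
            for chrom in chrom_names}
    ids_by_chrom = {chrom: [iv.id for iv in ccres if iv.chrom == chrom]
                    for chrom in chrom_names}
    genes: list[GenomicInterval] = []
    gene_rows = []
    for g in range(config.n_genes):
        gid = f"gene_{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if g < len(anchors):
            anchor = by_id[anchors[g]]
            offset = int(rng.integers(-100_000, 100_001))
            pos = int(np.clip(anchor.midpoint + offset, 0,
                              layout.length(anchor.chrom) - 1))
            chrom = anchor.chrom
            links = [anchor.id]
            if rng.random() < 0.15:  # a second linked element within the window
                m = mids[chrom]
                near = np.flatnonzero(np.abs(m - pos) <= 450_000)
                near_ids = [ids_by_chrom[chrom][j] for j in near
                            if ids_by_chrom[chrom][j] != anchor.id]
                if near_ids:
                    links.append(near_ids[int(rng.integers(len(near_ids)))])
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(0, layout.length(chrom)))
            links = []
        genes.append(GenomicInterval(chrom, pos, pos + 1, gid, strand))
        gene_rows.append({"gene_id": gid, "linked_ccres": ",".join(links),
                          "rho": config.rna_link_rho if links else 0.0})

    truth = TruthTables(
        ccres=pd.DataFrame({
            "ccre_id": [iv.id for iv in ccres],
            "chrom": [iv.chrom for iv in ccres],
            "start": [iv.start for iv in ccres],
            "end": [iv.end for iv in ccres],
            "direction": [direction[iv.id] for iv in ccres],
            "cell_type": [affected_ct[iv.id] for iv in ccres],
            "fold": [config.age_fold if direction[iv.id] != "null" else 1.0
                     for iv in ccres],
            "cluster_id": [cluster_of[iv.id] or "" for iv in ccres],
        }),
        genes=pd.DataFrame(gene_rows),
        domains=pd.DataFrame({
            "domain_id": [d.id for d in domains],
            "chrom": [d.chrom for d in domains],
            "start": [d.start for d in domains],
            "end": [d.end for d in domains],
            "decaying": [i in decaying_idx for i in range(config.n_domains)],
            "delta": [config.domain_decay if i in decaying_idx else 0.0
                      for i in range(config.n_domains)],
        }),
        clusters=pd.DataFrame({
            "cluster_id": [c.id for c in clusters],
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "domain_id": [domains[di].id for di in host_idx],
            "cell_type": [EXN] * len(clusters),
            "n_ccres": [config.ccres_per_cluster] * len(clusters),
        }),
    )
    return Annotation(layout, ccres, genes, list(domains), truth)


# ---------------------------------------------------------------------------
# counts


@dataclass
class SimCounts:
    atac: CountMatrix                 # cCREs x (cell type, age, rep)
    rna: CountMatrix                  # genes x (cell type, age, rep)
    k9_domains: CountMatrix           # domains x (cell type, age, rep)
    cell_domain_reads: pd.DataFrame   # per-cell K9 read-to-domain assignments
    k9_positions: dict                # chrom -> aggregated K9 read positions


def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))


def _fold_matrix(truth_ccres: pd.DataFrame, config: SimConfig,
                 cell_types: list[str]) -> dict[tuple[str, int], np.ndarray]:
    """Per-(cell type, age) multiplicative age factor per feature."""
    step = config.age_step
    base = np.ones(len(truth_ccres))
    out = {}
    sign = truth_ccres["direction"].map({"up": 1.0, "down": -1.0, "null": 0.0})
    sign = sign.to_numpy()
    for ct in cell_types:
        hit = (truth_ccres["cell_type"] == ct).to_numpy()
        for age in config.ages:
            f = base.copy()
            expo = sign * step[age]
            f[hit] = config.age_fold ** expo[hit]
            out[(ct, age)] = f
    return out


def generate_counts(annotation: Annotation, config: SimConfig) -> SimCounts:
    """NB count matrices for ATAC, RNA and H3K9me3 domains, plus per-cell data.

    ATAC means: per-cCRE lognormal baseline x per-(cCRE, cell type)
    lognormal factor x age fold, normalised so each pseudo-bulk column
    has the configured expected depth. RNA for linked genes follows the
    summed expected CPM of the linked cCREs through a shared latent
    activity with lognormal noise calibrated to the target correlation.
    H3K9me3 domain means are proportional to domain length, scaled in
    decaying domains of the ExN-like cell type by (1 - delta*step/2).
    """
    cfg = config
    truth = annotation.truth
    cell_types = cfg.cell_types
    keys = cfg.sample_keys()
    step = cfg.age_step

    # --- ATAC ---
    rng = _rng(cfg.seed, 1)
    n = len(annotation.ccres)
    baseline = rng.lognormal(cfg.ccre_mu_log, cfg.ccre_sigma_log, n)
    ct_factor = {ct: rng.lognormal(0.0, cfg.celltype_sigma, n)
                 for ct in cell_types}
    folds = _fold_matrix(truth.ccres, cfg, cell_types)
    atac_mean = np.empty((n, len(keys)))
    for j, (ct, age, rep) in enumerate(keys):
        w = baseline * ct_factor[ct] * folds[(ct, age)]
        atac_mean[:, j] = cfg.library_size * w / w.sum()
    atac_counts = _nb_draw(rng, atac_mean, cfg.dispersion)
    samples = [SampleKey(ct, age, rep, cfg.cells_per_sample, 0)
               for ct, age, rep in keys]
    atac = CountMatrix([iv.id for iv in annotation.ccres], samples,
                       atac_counts).with_library_sizes_from_counts()

    # expected CPM per (cell type, age) data point, for the RNA coupling
    cpm_mean = {}
    for ct in cell_types:
        for age in cfg.ages:
            w = baseline * ct_factor[ct] * folds[(ct, age)]
            cpm_mean[(ct, age)] = 1e6 * w / w.sum()

    # --- RNA ---
    rng = _rng(cfg.seed, 2)
    g = len(annotation.genes)
    gene_base = rng.lognormal(0.0, 1.0, g)
    gene_ct = {ct: rng.lognormal(0.0, cfg.celltype_sigma, g)
               for ct in cell_types}
    ccre_index = {iv.id: i for i, iv in enumerate(annotation.ccres)}
    dps = [(ct, age) for ct in cell_types for age in sorted(cfg.ages)]
    x = np.empty((g, len(dps)))  # latent expression weight per data point
    linked_rows = truth.genes["linked_ccres"].tolist()
    v_meas = cfg.dispersion / cfg.n_replicates  # count-level log variance
    for gi, linked in enumerate(linked_rows):
        if linked:
            idx = [ccre_index[c] for c in linked.split(",")]
            a = np.array([cpm_mean[dp][idx].sum() for dp in dps])
            la = np.log(a)
            s2 = la.var()
            rho = cfg.rna_link_rho
            # Correlation is measured on CPM levels, which for jointly
            # lognormal variables is attenuated relative to the log
            # scale: corr_level = (e^cov - 1)/sqrt((e^Va - 1)(e^Vr - 1))
            # with Va = s2 + v_a, Vr = s2 + tau2 + v_r. Solve for the
            # gene noise tau2 that puts the level correlation at the
            # target (0 if even noiseless coupling falls short).
            ea = np.expm1(s2 + v_meas)
            target_evr = (np.expm1(s2) / (rho * np.sqrt(ea))) ** 2
            tau2 = max(0.0, np.log1p(target_evr) - s2 - v_meas)
            # centre the log-latent so linked genes share the library
            # on the same scale as unlinked ones
            x[gi] = np.exp(la - la.mean()
                           + rng.normal(0.0, np.sqrt(tau2), len(dps)))
        else:
            x[gi] = gene_base[gi] * np.array(
                [gene_ct[ct][gi] for ct, _ in dps])
    dp_index = {dp: k for k, dp in enumerate(dps)}
    rna_mean = np.empty((g, len(keys)))
    for j, (ct, age, rep) in enumerate(keys):
        col = x[:, dp_index[(ct, age)]]
        rna_mean[:, j] = cfg.rna_library_size * col / col.sum()
    rna_counts = _nb_draw(rng, rna_mean, cfg.dispersion)
    rna = CountMatrix([iv.id for iv in annotation.genes],
                      [SampleKey(ct, age, rep, cfg.cells_per_sample, 0)
                       for ct, age, rep in keys],
                      rna_counts).with_library_sizes_from_counts()

    # --- H3K9me3 domain counts ---
    # k9_library_size is the total per-sample depth; a fixed
    # k9_in_domain_fraction of it falls inside domains at baseline and the
    # rest is genomic background. Decay removes in-domain reads rather than
    # redistributing them, and the sample library size used for offsets is
    # the full depth (in-domain + background), as with a real library —
    # normalising to the in-domain sum alone would turn decay in one
    # domain subset into spurious gains everywhere else.
    rng = _rng(cfg.seed, 3)
    dom = truth.domains
    d_len = (dom["end"] - dom["start"]).to_numpy(dtype=float)
    decaying = dom["decaying"].to_numpy(dtype=bool)
    in_dom_base = cfg.k9_library_size * cfg.k9_in_domain_fraction
    bg_mean = cfg.k9_library_size * (1.0 - cfg.k9_in_domain_fraction)
    k9_mean = np.empty((len(dom), len(keys)))
    for j, (ct, age, rep) in enumerate(keys):
        w = d_len.copy()
        if ct == EXN:
            w[decaying] *= 1.0 - cfg.domain_decay * step[age] / 2.0
        k9_mean[:, j] = in_dom_base * w / d_len.sum()
    k9_counts = _nb_draw(rng, k9_mean, cfg.domain_dispersion)
    k9_background = _nb_draw(rng, np.full(len(keys), bg_mean),
                             cfg.domain_dispersion)
    k9 = CountMatrix(
        dom["domain_id"].tolist(),
        [SampleKey(ct, age, rep, cfg.cells_per_sample,
                   int(k9_counts[:, j].sum() + k9_background[j]))
         for j, (ct, age, rep) in enumerate(keys)],
        k9_counts)

    # --- per-cell K9 read-to-domain assignments (FRiP substrate) ---
    rng = _rng(cfg.seed, 4)
    rows = []
    p_dom_total = cfg.k9_in_domain_fraction
    dom_w = d_len / d_len.sum()
    for ct in cell_types:
        for age in sorted(cfg.ages):
            w = dom_w.copy()
            if ct == EXN:
                w = w * np.where(
                    decaying, 1.0 - cfg.domain_decay * step[age] / 2.0, 1.0)
            probs = np.concatenate([p_dom_total * w,
                                    [1.0 - p_dom_total * w.sum()]])
            probs /= probs.sum()
            totals = rng.poisson(cfg.k9_reads_per_cell, cfg.cells_per_sample)
            totals = np.maximum(totals, 1)
            draws = rng.multinomial(totals, probs)
            for c in range(cfg.cells_per_sample):
                row = {"barcode": f"{ct}.{age}.c{c:04d}", "cell_type": ct,
                       "age_months": age, "total": int(totals[c])}
                for di, did in enumerate(dom["domain_id"]):
                    row[did] = int(draws[c, di])
                rows.append(row)
    cell_domain_reads = pd.DataFrame(rows)

    # --- aggregated K9 read positions for broad-domain calling ---
    rng = _rng(cfg.seed, 5)
    k9_positions = {}
    for chrom, length in annotation.layout:
        lam_bg = cfg.k9_background_per_5kb / 5000.0
        n_bg = rng.poisson(lam_bg * length)
        pos = [rng.integers(0, length, size=n_bg)]
        for _, d in dom[dom["chrom"] == chrom].iterrows():
            extra = rng.poisson(lam_bg * (cfg.k9_domain_enrichment - 1.0)
                                * (d["end"] - d["start"]))
            pos.append(rng.integers(d["start"], d["end"], size=extra))
        k9_positions[chrom] = np.sort(np.concatenate(pos))

    return SimCounts(atac=atac, rna=rna, k9_domains=k9,
                     cell_domain_reads=cell_domain_reads,
                     k9_positions=k9_positions)


# ---------------------------------------------------------------------------
# fragments


def generate_fragments(
    annotation: Annotation,
    config: SimConfig,
    n_barcodes: int = 200,
) -> tuple[list[FragmentRecord], dict[str, SampleKey]]:
    """Barcoded fragments with a TSS-centred insertion pile-up.

    Insertion sites are drawn from a mixture of a genome-wide uniform
    background and a flat plateau of half-width
    ``tss_plateau_halfwidth`` around each TSS, weighted so the plateau
    is ``tss_fold`` times the background density. Each fragment is a
    short stylised tag whose two Tn5 cut sites (after the +4/-5 strand
    shifts) coincide at the drawn position, so the downstream enrichment
    score estimates ``tss_fold`` directly.

    A ``lowq_fraction`` of barcodes is degraded for filter testing:
    half get fewer than 500 fragments, half get background-only
    insertions (TSS enrichment ~ 1).
    """
    cfg = config
    rng = _rng(cfg.seed, 6)
    layout = annotation.layout
    chrom_names = list(layout.names)
    lengths = np.array([layout.length(c) for c in chrom_names], dtype=float)
    genome_bp = lengths.sum()
    tss = annotation.genes
    width = 2 * cfg.tss_plateau_halfwidth + 1
    extra_mass = len(tss) * width * (cfg.tss_fold - 1.0)
    p_tss = extra_mass / (genome_bp + extra_mass) if extra_mass > 0 else 0.0

    tss_chrom = np.array([chrom_names.index(t.chrom) for t in tss])
    tss_pos = np.array([t.start for t in tss])

    keys = cfg.sample_keys()
    mapping: dict[str, SampleKey] = {}
    fragments: list[FragmentRecord] = []
    n_lowq = int(round(cfg.lowq_fraction * n_barcodes))
    lowq_kind = (["sparse", "background"] * n_barcodes)[:n_lowq]
    for b in range(n_barcodes):
        ct, age, rep = keys[b % len(keys)]
        barcode = f"BC{b:05d}"
        mapping[barcode] = SampleKey(ct, age, rep, cfg.cells_per_sample, 0)
        kind = lowq_kind[b] if b < n_lowq else "good"
        if kind == "sparse":
            n_frag = int(rng.integers(50, 400))
        else:
            n_frag = int(rng.lognormal(np.log(cfg.frags_per_barcode_median),
                                       cfg.frags_per_barcode_sigma))
            n_frag = max(n_frag, 600)
        from_tss = (rng.random(n_frag) < p_tss) if kind != "background" \
            else np.zeros(n_frag, dtype=bool)
        ci = rng.integers(0, len(chrom_names), size=n_frag)
        pos = (rng.random(n_frag) * lengths[ci]).astype(np.int64)
        n_t = int(from_tss.sum())
        if n_t:
            ti = rng.integers(0, len(tss), size=n_t)
            offs = rng.integers(-cfg.tss_plateau_halfwidth,
                                cfg.tss_plateau_halfwidth + 1, size=n_t)
            ci[from_tss] = tss_chrom[ti]
            pos[from_tss] = tss_pos[ti] + offs
        pos = np.clip(pos, 4, (lengths[ci] - 7).astype(np.int64))
        for c, p in zip(ci, pos):
            fragments.append(FragmentRecord(chrom_names[int(c)], int(p) - 4,
                                            int(p) + 6, barcode))
    return fragments, mapping
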