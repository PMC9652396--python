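"""Properties of the synthetic-study generator and its truth tables."""

import numpy as np
import pandas as pd
import pytest

from chromage.qc import filter_nuclei, per_barcode_stats, tss_enrichment
from chromage.simulate import (EXN, SimConfig, generate_annotation,
                               generate_counts, generate_fragments)


class TestAnnotation:
    def test_deterministic_given_seed(self, default_config, annotation):
        again = generate_annotation(SimConfig(seed=default_config.seed))
        assert again.ccres == annotation.ccres
        assert again.genes == annotation.genes
        assert again.domains == annotation.domains
        for name in ("ccres", "genes", "domains", "clusters"):
            pd.testing.assert_frame_equal(getattr(again.truth, name),
                                          getattr(annotation.truth, name))

    def test_ccres_disjoint_and_sized(self, annotation):
        by_chrom = {}
        for iv in annotation.ccres:
            assert 200 <= len(iv) <= 1000
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda v: v.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_cluster_ccres_inside_decaying_domains(self, annotation):
        truth = annotation.truth
        decaying = truth.domains[truth.domains["decaying"]]
        spans = [(r.chrom, r.start, r.end) for r in decaying.itertuples()]
        members = truth.ccres[truth.ccres["cluster_id"] != ""]
        assert len(members) > 0
        for row in members.itertuples():
            assert row.direction == "up" and row.cell_type == EXN
            assert any(c == row.chrom and s <= row.start and row.end <= e
                       for c, s, e in spans)

    def test_domains_disjoint_and_large(self, annotation):
        doms = sorted(annotation.domains, key=lambda d: (d.chrom, d.start))
        for a, b in zip(doms, doms[1:]):
            assert a.chrom != b.chrom or a.end <= b.start
        assert all(len(d) >= 100_000 for d in annotation.domains)

    def test_no_domains_degenerate_config_runs(self):
        cfg = SimConfig(seed=3, n_domains=0, n_clusters=0,
                        fraction_decaying_domains=0.0)
        ann = generate_annotation(cfg)
        assert ann.domains == [] and len(ann.truth.clusters) == 0
        sim = generate_counts(ann, cfg)
        assert sim.atac.counts.shape[0] == cfg.n_ccres

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            generate_annotation(SimConfig(seed=1, n_ccres=500_000))

    def test_linked_genes_reference_existing_ccres(self, annotation):
        ids = {iv.id for iv in annotation.ccres}
        for row in annotation.truth.genes.itertuples():
            for c in (row.linked_ccres.split(",") if row.linked_ccres else []):
                assert c in ids


class TestCounts:
    def test_counts_nonnegative_and_library_sizes_match(self, sim_counts):
        for mat in (sim_counts.atac, sim_counts.rna):
            assert np.all(mat.counts >= 0)
            assert np.array_equal(mat.counts.sum(axis=0),
                                  [s.library_size for s in mat.samples])

    def test_same_seed_identical_matrices(self, default_config, annotation,
                                          sim_counts):
        again = generate_counts(annotation, default_config)
        assert np.array_equal(again.atac.counts, sim_counts.atac.counts)
        assert np.array_equal(again.rna.counts, sim_counts.rna.counts)
        assert np.array_equal(again.k9_domains.counts,
                              sim_counts.k9_domains.counts)

    def test_planted_fold_reaches_full_two_step_ratio(self):
        # fold 1.5 per age step: 18 mo / 3 mo mean ratio = 1.5^2 = 2.25
        cfg = SimConfig(seed=7, n_ccres=2000, n_genes=50, n_clusters=0,
                        fraction_age_up=0.1, fraction_age_down=0.0,
                        celltype_sigma=0.0)
        ann = generate_annotation(cfg)
        sim = generate_counts(ann, cfg)
        truth = ann.truth.ccres
        up = truth[(truth["direction"] == "up")]
        assert len(up) >= 180
        mat = sim_cpm = sim.atac
        cols3 = [j for j, s in enumerate(mat.samples) if s.age_months == 3]
        cols18 = [j for j, s in enumerate(mat.samples) if s.age_months == 18]
        ratios = []
        for row in up.itertuples():
            i = mat.feature_ids.index(row.ccre_id)
            ct_cols3 = [j for j in cols3
                        if mat.samples[j].cell_type == row.cell_type]
            ct_cols18 = [j for j in cols18
                        if mat.samples[j].cell_type == row.cell_type]
            ratios.append(mat.counts[i, ct_cols18].mean()
                          / max(mat.counts[i, ct_cols3].mean(), 1e-9))
        assert np.mean(ratios) == pytest.approx(2.25, rel=0.10)

    def test_null_config_gives_nominal_differential_rate(self):
        from chromage.pipeline import differential_by_cell_type
        cfg = SimConfig(seed=11, fraction_age_up=0.0, fraction_age_down=0.0,
                        n_clusters=0, domain_decay=0.0)
        ann = generate_annotation(cfg)
        sim = generate_counts(ann, cfg)
        recs = differential_by_cell_type(sim.atac)[EXN]
        rate = np.mean([r.p_value < 0.01 for r in recs])
        assert 0.003 <= rate <= 0.025

    def test_monotone_age_trend_for_planted_features(self, sim_counts,
                                                     annotation):
        mat = sim_counts.atac
        truth = annotation.truth.ccres
        up = truth[truth["direction"] == "up"].head(50)
        cols = {age: [j for j, s in enumerate(mat.samples)
                      if s.age_months == age and s.cell_type == EXN]
                for age in (3, 10, 18)}
        means = []
        for row in up[up["cell_type"] == EXN].itertuples():
            i = mat.feature_ids.index(row.ccre_id)
            means.append([mat.counts[i, cols[a]].mean() for a in (3, 10, 18)])
        means = np.array(means).mean(axis=0)
        assert means[0] < means[1] < means[2]


class TestFragments:
    def test_uniform_limit_scores_near_one(self):
        # the max-of-smoothed score is upward-biased on sparse flat
        # profiles; a dense TSS layout keeps most events in-window so the
        # uniform limit is measured at adequate depth
        cfg = SimConfig(seed=5, chromosomes=(("chr1", 2_000_000),
                                             ("chr2", 2_000_000)),
                        n_ccres=500, n_genes=600, n_domains=0, n_clusters=0,
                        tss_fold=1.0, lowq_fraction=0.0)
        ann = generate_annotation(cfg)
        frags, _ = generate_fragments(ann, cfg, n_barcodes=200)
        score = tss_enrichment(frags, ann.genes).score
        assert abs(score - 1.0) < 0.2

    def test_configured_fold_recovered(self, annotation, default_config,
                                       fragments_and_map):
        frags, _ = fragments_and_map
        assert len(frags) >= 400_000
        score = tss_enrichment(frags, annotation.genes).score
        assert abs(score - default_config.tss_fold) / default_config.tss_fold \
            <= 0.20

    def test_low_quality_fraction_fails_filter(self, annotation):
        # Expected failure fraction from the generative model: all "sparse"
        # barcodes fail the 500-fragment cutoff; "background" barcodes have
        # sparse-profile scores of roughly 4-15, so only most fail the
        # TSS >= 10 cutoff; good barcodes essentially always pass.
        cfg = SimConfig(seed=9, lowq_fraction=0.2)
        frags, _ = generate_fragments(annotation, cfg, n_barcodes=200)
        stats = per_barcode_stats(frags, annotation.genes)
        kept = set(filter_nuclei(stats))
        fail = 1 - len(kept) / len(stats)
        assert 0.12 <= fail <= 0.25

    def test_mapping_covers_all_barcodes(self, fragments_and_map):
        frags, mapping = fragments_and_map
        assert {f.barcode for f in frags} <= set(mapping)
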