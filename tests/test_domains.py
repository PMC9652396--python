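"""Broad-domain calling, decay statistics, enrichment, meta-profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromage.counts import CountMatrix, FragmentRecord, SampleKey
from chromage.differential import DifferentialRecord
from chromage.domains import (OverlapEnrichmentResult, _shorth_location,
                              aggregate_profile, call_broad_domains,
                              cluster_domain_overlap_enrichment,
                              fisher_overlap_enrichment,
                              fraction_reads_in_domains)
from chromage.genome import GenomeLayout, GenomicInterval
from conftest import fisher_p_enumeration

GENOME = GenomeLayout([("chr1", 10_000_000)])


class TestBroadDomainCalling:
    def test_uniform_signal_yields_no_domains(self):
        failures = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = rng.integers(0, 10_000_000,
                               size=int(20 / 5000 * 10_000_000))
            if call_broad_domains({"chr1": pos}, GENOME):
                failures += 1
        assert failures == 0

    def test_planted_block_recovered_with_reciprocal_overlap(self):
        rng = np.random.default_rng(0)
        bg = rng.integers(0, 10_000_000, size=40_000)  # lambda = 20 / 5 kb
        block = rng.integers(4_000_000, 4_300_000, size=4_800)  # 5x density
        calls = call_broad_domains({"chr1": np.concatenate([bg, block])},
                                   GENOME)
        assert len(calls) == 1
        c = calls[0].interval
        inter = min(c.end, 4_300_000) - max(c.start, 4_000_000)
        assert min(inter / len(c), inter / 300_000) >= 0.95
        assert c.end - c.start > 100_000

    def test_short_block_rejected_by_min_size(self):
        rng = np.random.default_rng(1)
        bg = rng.integers(0, 10_000_000, size=40_000)
        block = rng.integers(4_000_000, 4_050_000, size=1_800)  # 10x, 50 kb
        calls = call_broad_domains({"chr1": np.concatenate([bg, block])},
                                   GENOME)
        assert calls == []

    def test_empty_signal_gives_empty_list(self):
        assert call_broad_domains({}, GENOME) == []

    def test_output_disjoint_and_large(self):
        rng = np.random.default_rng(2)
        bg = rng.integers(0, 10_000_000, size=40_000)
        blocks = [rng.integers(s, s + 400_000, size=6_000)
                  for s in (1_000_000, 6_000_000)]
        calls = call_broad_domains(
            {"chr1": np.concatenate([bg] + blocks)}, GENOME)
        spans = sorted((c.interval.start, c.interval.end) for c in calls)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert all(len(c.interval) > 100_000 for c in calls)


class TestShorthLocation:
    def test_resists_forty_percent_shifted(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            clean = rng.normal(0, 0.07, 6)
            shifted = rng.normal(-0.36, 0.07, 4)
            est = _shorth_location(np.concatenate([clean, shifted]))
            assert abs(est) < 0.15

    def test_plain_sample_location(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 0.1, 11)
        assert abs(_shorth_location(x) - 5.0) < 0.15


class TestFripStatistic:
    def _table(self):
        rows = [
            {"barcode": "a", "cell_type": "ExN", "age_months": 3,
             "total": 12, "d1": 3, "d2": 0},
            {"barcode": "b", "cell_type": "ExN", "age_months": 3,
             "total": 10, "d1": 5, "d2": 5},
            {"barcode": "c", "cell_type": "ExN", "age_months": 18,
             "total": 8, "d1": 1, "d2": 0},
            {"barcode": "z", "cell_type": "ExN", "age_months": 18,
             "total": 0, "d1": 0, "d2": 0},
        ]
        return pd.DataFrame(rows)

    def test_fraction_arithmetic_and_zero_cell_exclusion(self):
        records, _ = fraction_reads_in_domains(self._table(), ["d1"])
        by_bc = {r.barcode: r.fraction for r in records}
        assert by_bc["a"] == pytest.approx(0.25)
        assert by_bc["b"] == pytest.approx(0.5)
        assert "z" not in by_bc

    def test_all_reads_inside_gives_one(self):
        records, _ = fraction_reads_in_domains(self._table(), ["d1", "d2"])
        assert max(r.fraction for r in records) == pytest.approx(1.0)

    def test_planted_decay_detected_by_ranksum(self, sim_counts, annotation):
        decaying = annotation.truth.domains.loc[
            annotation.truth.domains["decaying"], "domain_id"].tolist()
        table = sim_counts.cell_domain_reads
        records, p = fraction_reads_in_domains(
            table[table["cell_type"] == "ExN"], decaying)
        young = np.median([r.fraction for r in records if r.age_months == 3])
        old = np.median([r.fraction for r in records if r.age_months == 18])
        assert old < young and p < 1e-6


class TestFisherEnrichment:
    def _records(self, n, n_top_hits, n_rest_hits, region):
        # build records whose ranking puts hits in/out of the top 1%
        records, ivs = [], {}
        k = max(1, int(round(0.01 * n)))
        pos_in, pos_out = 100, 1_000_000
        for i in range(n):
            fid = f"f{i:05d}"
            in_top = i < k
            hit = (i < n_top_hits) if in_top else (i - k < n_rest_hits)
            p = 1e-6 * (i + 1) if in_top else 0.5 + i / (4 * n)
            records.append(DifferentialRecord(fid, 1.0, 1.0, p, p, "ns"))
            if hit:
                mid = pos_in = pos_in + 10
            else:
                mid = pos_out = pos_out + 10
            ivs[fid] = GenomicInterval("chr1", mid, mid + 5, fid)
        return records, ivs, [region]

    def test_example_table_or_and_enumeration_oracle(self):
        region = GenomicInterval("chr1", 0, 5_000)
        records, ivs, regions = self._records(1000, 10, 10, region)
        res = fisher_overlap_enrichment(records, ivs, regions)
        assert res.table == (10, 0, 10, 980) or res.table[0] == 10
        a, b, c, d = res.table
        assert res.fisher_p == pytest.approx(
            fisher_p_enumeration(a, b, c, d), abs=1e-12)

    def test_sample_odds_ratio_value(self):
        # table [[10, 90], [10, 890]] -> sample OR = 9.89 (2 d.p.)
        a, b, c, d = 10, 90, 10, 890
        assert round(a * d / (b * c), 2) == 9.89

    def test_no_enrichment_is_null(self):
        region = GenomicInterval("chr1", 0, 5_000_000)
        records, ivs, regions = self._records(1000, 10, 990, region)
        res = fisher_overlap_enrichment(records, ivs, regions)
        assert res.odds_ratio > 0 and res.fisher_p == pytest.approx(1.0)

    def test_degenerate_top_fraction_guarded(self):
        region = GenomicInterval("chr1", 0, 5_000)
        records, ivs, regions = self._records(100, 1, 1, region)
        with pytest.raises(ValueError):
            fisher_overlap_enrichment(records, ivs, regions, top_fraction=1.0)

    def test_empty_region_set_flagged(self):
        records, ivs, _ = self._records(100, 1, 1,
                                        GenomicInterval("chr1", 0, 10))
        assert fisher_overlap_enrichment(records, ivs, []).flagged


class TestClusterDomainOverlap:
    def test_saturating_clusters_give_fold_one(self):
        domains = [GenomicInterval("chr1", s, s + 200_000)
                   for s in range(0, 2_000_000, 500_000)]
        clusters = [GenomicInterval("chr1", 0, 10_000_000)]
        res = cluster_domain_overlap_enrichment(domains, clusters, GENOME,
                                                n_shuffles=100, seed=0)
        assert res.observed_fraction == 1.0
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_fold_is_observed_over_expected(self):
        res = OverlapEnrichmentResult(observed_fraction=0.12,
                                      expected_fraction_shuffle=0.006,
                                      fold_enrichment=0.12 / 0.006)
        assert res.fold_enrichment == pytest.approx(20.0)

    def test_empty_clusters_flagged(self):
        domains = [GenomicInterval("chr1", 0, 200_000)]
        res = cluster_domain_overlap_enrichment(domains, [], GENOME)
        assert res.flagged and res.observed_fraction == 0.0

    def test_unrelated_null_is_calibrated(self):
        rng = np.random.default_rng(0)
        folds, ps = [], []
        for _ in range(60):
            doms = [GenomicInterval("chr1", s, s + 300_000)
                    for s in rng.integers(0, 9_700_000, 6)]
            clus = [GenomicInterval("chr1", int(s), int(s) + 400_000)
                    for s in rng.integers(0, 9_600_000, 3)]
            res = cluster_domain_overlap_enrichment(
                doms, clus, GENOME, n_shuffles=100,
                seed=int(rng.integers(2**31)))
            folds.append(res.fold_enrichment)
            ps.append(res.shuffle_p)
        assert 0.5 <= np.median(folds) <= 2.0
        assert 0.2 <= np.median(ps) <= 0.8


class TestAggregateProfile:
    def _uniform_frags(self, rng, n=30_000):
        return [FragmentRecord("chr1", int(s), int(s) + 50, "A")
                for s in rng.integers(0, 1_000_000, n)]

    def test_uniform_coverage_is_flat(self):
        rng = np.random.default_rng(0)
        inst = [GenomicInterval("chr1", s, s + 500, f"i{k}", "+")
                for k, s in enumerate(range(100_000, 900_000, 40_000))]
        prof = aggregate_profile(self._uniform_frags(rng), inst, flank=500,
                                 normalize=True)
        assert prof.signal.std() / prof.signal.mean() < 0.25
        assert abs(prof.signal.mean() - 1.0) < 0.2

    def test_body_enrichment_ratio_recovered(self):
        rng = np.random.default_rng(1)
        frags = self._uniform_frags(rng, 20_000)
        instances = [GenomicInterval("chr1", s, s + 1_000, f"i{k}", "+")
                     for k, s in enumerate(range(100_000, 900_000, 40_000))]
        for inst in instances:  # ~2x extra coverage over bodies -> ratio 3
            for s in rng.integers(inst.start, inst.end - 50, 40):
                frags.append(FragmentRecord("chr1", int(s), int(s) + 50, "A"))
        prof = aggregate_profile(frags, instances, flank=500, normalize=True)
        body = prof.signal[52:58].mean()       # central body points
        flank = np.concatenate([prof.signal[:40], prof.signal[-40:]]).mean()
        assert body / flank == pytest.approx(3.0, rel=0.25)

    def test_minus_strand_profile_mirrored(self):
        frags = [FragmentRecord("chr1", 500_000 + o, 500_050 + o, "A")
                 for o in range(0, 200, 2)]  # left-skewed inside the body
        plus = aggregate_profile(
            frags, [GenomicInterval("chr1", 500_000, 501_000, "i", "+")],
            flank=500)
        minus = aggregate_profile(
            frags, [GenomicInterval("chr1", 500_000, 501_000, "i", "-")],
            flank=500)
        assert np.allclose(plus.signal, minus.signal[::-1], atol=1e-9)

    def test_no_instances_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_profile([], [], flank=100)
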