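"""Binning, Gaussian density smoothing and permutation cluster calling."""

import numpy as np
import pytest

from chromage.clusters import (BinTrack, bin_differential_counts,
                               call_ccre_clusters, gaussian_smooth)
from chromage.differential import DifferentialRecord
from chromage.genome import GenomeLayout, GenomicInterval

GENOME = GenomeLayout([("chr1", 5_000_000), ("chr2", 3_050_000)])


def rec(fid, p, lfc=1.0):
    return DifferentialRecord(fid, lfc, 1.0, p, p, "ns")


def ccre(fid, chrom, mid):
    return GenomicInterval(chrom, mid - 100, mid + 100, fid)


class TestBinning:
    def test_midpoint_assignment(self):
        ivs = {"a": ccre("a", "chr1", 250_000)}
        track = bin_differential_counts([rec("a", 5e-4)], ivs, GENOME)
        assert track.counts["chr1"][2] == 1
        assert track.counts["chr1"].sum() == 1
        assert track.counts["chr2"].sum() == 0

    def test_subthreshold_record_excluded(self):
        ivs = {"a": ccre("a", "chr1", 250_000)}
        track = bin_differential_counts([rec("a", 0.002)], ivs, GENOME)
        assert track.total == 0

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        ivs, records = {}, []
        for i in range(500):
            fid = f"c{i}"
            ivs[fid] = ccre(fid, "chr1", int(rng.integers(200, 4_999_800)))
            records.append(rec(fid, 1e-4))
        track = bin_differential_counts(records, ivs, GENOME)
        assert track.total == 500

    def test_partial_last_bin_kept(self):
        ivs = {"a": ccre("a", "chr2", 3_020_000)}
        track = bin_differential_counts([rec("a", 1e-4)], ivs, GENOME)
        assert len(track.counts["chr2"]) == 31
        assert track.counts["chr2"][30] == 1

    def test_missing_interval_is_an_error(self):
        with pytest.raises(KeyError, match="ghost"):
            bin_differential_counts([rec("ghost", 1e-4)], {}, GENOME)

    def test_direction_restriction(self):
        ivs = {"a": ccre("a", "chr1", 150_000),
               "b": ccre("b", "chr1", 250_000)}
        records = [rec("a", 1e-4, lfc=2.0), rec("b", 1e-4, lfc=-2.0)]
        up = bin_differential_counts(records, ivs, GENOME, direction="up")
        assert up.diff_ids == {"a"}


class TestSmoothing:
    def _track(self, counts_chr1):
        counts = {"chr1": np.asarray(counts_chr1, dtype=np.int64),
                  "chr2": np.zeros(31, dtype=np.int64)}
        return BinTrack(GENOME, 100_000, counts, set())

    def test_zero_track_stays_zero(self):
        sm = gaussian_smooth(self._track(np.zeros(50, dtype=int)))
        assert np.all(sm.scores["chr1"] == 0)

    def test_single_spike_equals_scaled_kernel(self):
        counts = np.zeros(50, dtype=int)
        counts[25] = 7
        sm = gaussian_smooth(self._track(counts))
        offs = np.arange(-10, 11)
        kernel = np.exp(-(offs**2) / (2 * 5.0**2))
        kernel /= kernel.sum()
        assert np.allclose(sm.scores["chr1"][15:36], 7 * kernel)
        assert int(np.argmax(sm.scores["chr1"])) == 25

    def test_mass_conserved_even_at_edges(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=50)
        counts[0] += 5
        counts[-1] += 5
        sm = gaussian_smooth(self._track(counts))
        assert sm.scores["chr1"].sum() == pytest.approx(counts.sum(),
                                                        rel=1e-9)

    def test_translation_equivariance(self):
        counts = np.zeros(60, dtype=int)
        counts[20:25] = [1, 4, 2, 3, 1]
        a = gaussian_smooth(self._track(counts)).scores["chr1"]
        b = gaussian_smooth(self._track(np.roll(counts, 1))).scores["chr1"]
        assert np.allclose(a[5:50], b[6:51])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(self._track(np.zeros(10, dtype=int)), window=0)


class TestClusterCalling:
    def _scatter(self, rng, n, exclude=()):
        out = {}
        while len(out) < n:
            mid = int(rng.integers(200, 4_999_800))
            if any(lo <= mid < hi for lo, hi in exclude):
                continue
            fid = f"s{len(out)}"
            out[fid] = ccre(fid, "chr1", mid)
        return out

    def test_planted_cluster_recovered(self):
        rng = np.random.default_rng(0)
        ivs = self._scatter(rng, 170, exclude=[(2_000_000, 3_000_000)])
        for i in range(30):  # dense planted block in 2.0-3.0 Mb
            fid = f"p{i}"
            ivs[fid] = ccre(fid, "chr1",
                            2_000_000 + int(rng.integers(1_000, 999_000)))
        records = ([rec(f"p{i}", 1e-5) for i in range(30)]
                   + [rec(f"s{i}", 1e-5) for i in range(10)]
                   + [rec(f"s{i}", 0.5) for i in range(10, 170)])
        track = bin_differential_counts(records, ivs, GENOME)
        sm = gaussian_smooth(track)
        calls = call_ccre_clusters(sm, track, list(ivs.values()),
                                   n_perm=500, seed=3)
        assert len(calls) == 1
        c = calls[0].interval
        inter = max(0, min(c.end, 3_000_000) - max(c.start, 2_000_000))
        assert min(inter / len(c), inter / 1_000_000) >= 0.5
        assert calls[0].n_members >= 5

    def test_no_differential_gives_no_calls(self):
        ivs = self._scatter(np.random.default_rng(1), 50)
        records = [rec(fid, 0.9) for fid in ivs]
        track = bin_differential_counts(records, ivs, GENOME)
        calls = call_ccre_clusters(gaussian_smooth(track), track,
                                   list(ivs.values()), n_perm=50, seed=0)
        assert calls == []

    def test_threshold_rises_as_fdr_level_falls(self):
        rng = np.random.default_rng(2)
        ivs = self._scatter(rng, 200)
        records = [rec(fid, 1e-4) for fid in list(ivs)[:40]] + [
            rec(fid, 0.5) for fid in list(ivs)[40:]]
        track = bin_differential_counts(records, ivs, GENOME)
        sm = gaussian_smooth(track)
        # stricter level -> higher threshold -> calls only shrink
        lengths = []
        for level in (0.05, 0.001):
            calls = call_ccre_clusters(sm, track, list(ivs.values()),
                                       n_perm=300, fdr_level=level,
                                       min_members=1, seed=5)
            lengths.append(sum(len(c.interval) for c in calls))
        assert lengths[1] <= lengths[0]

    def test_invariant_to_ccre_input_order(self):
        rng = np.random.default_rng(4)
        ivs = self._scatter(rng, 100)
        records = [rec(fid, 1e-4) for fid in list(ivs)[:30]]
        track = bin_differential_counts(records, ivs, GENOME)
        sm = gaussian_smooth(track)
        a = call_ccre_clusters(sm, track, list(ivs.values()), n_perm=200,
                               min_members=1, seed=9)
        b = call_ccre_clusters(sm, track, list(ivs.values())[::-1],
                               n_perm=200, min_members=1, seed=9)
        assert [c.interval for c in a] == [c.interval for c in b]
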