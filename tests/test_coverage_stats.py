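import numpy as np
import pytest

from locusforge.errors import InsufficientDataError, ParameterError
from locusforge.coverage_stats import (
    binned_correlation,
    count_reads_in_regions,
    estimate_copy_number,
    geneless_windows,
    lower_median,
    make_windows,
    mean_depth,
    peak_density,
    relative_coverage,
    rpgc_normalize,
)
from locusforge.io_formats import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    ReadRecord,
)


def track(values, resolution=1, **contigs):
    if contigs:
        return CoverageTrack({c: np.asarray(v, float) for c, v in contigs.items()},
                             resolution=resolution)
    return CoverageTrack({"chr1": np.asarray(values, float)}, resolution=resolution)


class TestMakeWindows:
    def test_sliding_window_count(self):
        ws = make_windows({"c": 300_000}, size=100_000, step=10_000)
        assert len(ws) == 21  # floor((300k - 100k) / 10k) + 1

    def test_short_contig_yields_no_windows(self):
        assert len(make_windows({"c": 50_000}, size=100_000, step=10_000)) == 0

    def test_step_equal_size_tiles_without_overlap(self):
        ws = make_windows({"c": 50_000}, size=10_000, step=10_000)
        assert [(w.start, w.end) for w in ws] == \
            [(i * 10_000, (i + 1) * 10_000) for i in range(5)]

    def test_keep_truncated_appends_clipped_tails(self):
        ws = make_windows({"c": 25_000}, size=10_000, step=10_000,
                          keep_truncated=True)
        assert [(w.start, w.end) for w in ws] == \
            [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]


class TestMeanDepth:
    def test_uniform_depth(self):
        t = track([3.0] * 10)
        assert mean_depth(t, GenomicInterval("chr1", 2, 8)) == 3.0

    def test_mixed_depth(self):
        t = track([0, 0, 6, 6])
        assert mean_depth(t, GenomicInterval("chr1", 0, 4)) == 3.0

    def test_equals_naive_per_base_loop(self, rng):
        values = rng.poisson(4, 1000).astype(float)
        t = track(values)
        region = GenomicInterval("chr1", 137, 856)
        naive = sum(values[i] for i in range(137, 856)) / (856 - 137)
        assert mean_depth(t, region) == pytest.approx(naive)


class TestCopyNumber:
    def test_uniform_two_copy_locus(self):
        t = track(None, genome=np.full(10_000, 30.0), locus=np.full(1_000, 60.0))
        est = estimate_copy_number(t, GenomicInterval("locus", 0, 1_000),
                                   exclude_contigs=("locus",))
        assert est.integer_call == 2
        assert est.estimate == pytest.approx(2.0)
        # with the locus contig left in the denominator the genome mean is
        # pulled up, but the nearest-integer call is unchanged
        inclusive = estimate_copy_number(t, GenomicInterval("locus", 0, 1_000),
                                         exclude_contigs=())
        assert inclusive.integer_call == 2

    def test_locus_equal_to_whole_genome_is_single_copy(self):
        t = track(np.full(5_000, 17.0))
        est = estimate_copy_number(t, GenomicInterval("chr1", 0, 5_000),
                                   exclude_contigs=())
        assert est.estimate == pytest.approx(1.0)

    def test_excluded_contig_ignored(self):
        t = track(None, chrA=np.full(1_000, 10.0), chrM=np.full(1_000, 1_000.0))
        est = estimate_copy_number(t, GenomicInterval("chrA", 0, 1_000))
        assert est.estimate == pytest.approx(1.0)

    def test_zero_genome_coverage_rejected(self):
        t = track([0.0] * 100)
        with pytest.raises(ParameterError):
            estimate_copy_number(t, GenomicInterval("chr1", 0, 10),
                                 exclude_contigs=())

    def test_two_copy_insertion_with_poisson_noise(self):
        rng = np.random.default_rng(42)
        genome = rng.poisson(30, 400_000).astype(float)
        locus = rng.poisson(60, 100_000).astype(float)
        t = track(None, genome=genome, locus=locus)
        est = estimate_copy_number(t, GenomicInterval("locus", 0, 100_000),
                                   exclude_contigs=("locus",))
        assert 1.9 <= est.estimate <= 2.1


class TestRpgcNormalize:
    def test_uniform_track_becomes_unit_depth(self):
        t = track([5.0] * 1_000)
        out = rpgc_normalize(t, effective_genome_size=1_000)
        assert np.allclose(out.data["chr1"], 1.0)

    def test_scale_invariance(self, rng):
        values = rng.poisson(7, 2_000).astype(float) + 1
        a = rpgc_normalize(track(values), 12_000)
        b = rpgc_normalize(track(values * 2), 12_000)
        np.testing.assert_allclose(a.data["chr1"], b.data["chr1"])

    def test_total_equals_effective_size(self, rng):
        values = rng.poisson(3, 500).astype(float) + 0.5
        out = rpgc_normalize(track(values), 12_000_000)
        assert out.total_signal() == pytest.approx(12_000_000)

    def test_zero_track_rejected(self):
        with pytest.raises(ParameterError):
            rpgc_normalize(track([0.0] * 10), 100)


class TestRelativeCoverage:
    def _setup(self, locus_depth, window_depth):
        t = track(None, genome=np.full(30_000, window_depth),
                  locus=np.full(1_000, locus_depth))
        ws = make_windows({"genome": 30_000}, size=10_000, step=10_000)
        return t, GenomicInterval("locus", 0, 1_000), ws

    def test_simple_ratio(self):
        t, locus, ws = self._setup(10.0, 5.0)
        rel = relative_coverage(t, locus, ws, copy_number=1)
        assert rel.relative == pytest.approx(2.0)

    def test_copy_correction(self):
        t, locus, ws = self._setup(10.0, 5.0)
        rel = relative_coverage(t, locus, ws, copy_number=2)
        assert rel.relative == pytest.approx(1.0)

    def test_invariant_to_global_rescaling(self, rng):
        values = rng.poisson(10, 30_000).astype(float) + 1
        t = CoverageTrack({"genome": values,
                           "locus": rng.poisson(20, 2_000) + 1.0})
        ws = make_windows({"genome": 30_000}, size=10_000, step=5_000)
        locus = GenomicInterval("locus", 0, 2_000)
        a = relative_coverage(t, locus, ws, 1.0)
        b = relative_coverage(t.scaled(7.3), locus, ws, 1.0)
        assert a.relative == pytest.approx(b.relative)

    def test_episome_at_four_copies_double_accessibility(self):
        # per-copy signal 2x the genome baseline, present at 4 copies
        rng = np.random.default_rng(7)
        baseline = 5.0
        t = CoverageTrack({
            "genome": rng.poisson(baseline, 200_000).astype(float),
            "episome": rng.poisson(4 * 2 * baseline, 20_000).astype(float),
        })
        ws = make_windows({"genome": 200_000}, size=20_000, step=20_000)
        rel = relative_coverage(t, GenomicInterval("episome", 0, 20_000), ws,
                                copy_number=4)
        assert rel.relative == pytest.approx(2.0, abs=0.1)


class TestPeakDensity:
    def test_region_scaling(self):
        peaks = PeakSet([GenomicInterval("c", i * 10_000, i * 10_000 + 100)
                         for i in range(5)])
        assert peak_density(peaks, region=GenomicInterval("c", 0, 100_000)) == 5.0
        assert peak_density(peaks, region=GenomicInterval("c", 0, 50_000)) == 10.0

    def test_midpoint_assignment(self):
        peaks = PeakSet([GenomicInterval("c", 90, 210)])  # midpoint 150
        ws = make_windows({"c": 300}, size=100, step=100)
        densities = [peak_density(peaks, region=w) for w in ws]
        assert densities == [0.0, 100_000 / 100, 0.0]

    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(11)
        genome_len, locus_len = 1_000_000, 100_000
        n_genome, n_locus = 40, 12  # density ratio 3
        peaks = [GenomicInterval("g", int(p), int(p) + 50)
                 for p in rng.integers(0, genome_len - 50, n_genome)]
        peaks += [GenomicInterval("L", int(p), int(p) + 50)
                  for p in rng.integers(0, locus_len - 50, n_locus)]
        ps = PeakSet(peaks)
        ws = make_windows({"g": genome_len}, size=100_000, step=10_000)
        locus_d = peak_density(ps, region=GenomicInterval("L", 0, locus_len))
        genome_d = peak_density(ps, windows=ws)
        planted = (n_locus / locus_len) / (n_genome / genome_len)
        assert locus_d / genome_d == pytest.approx(planted, rel=0.2)


class TestGenelessWindows:
    def test_no_exclusions_identity(self):
        ws = make_windows({"c": 100_000}, size=10_000, step=10_000)
        assert geneless_windows(ws, PeakSet([])).windows == ws.windows

    def test_full_contig_exclusion_removes_all(self):
        ws = make_windows({"c": 100_000}, size=10_000, step=10_000)
        out = geneless_windows(ws, PeakSet([GenomicInterval("c", 0, 100_000)]))
        assert len(out) == 0

    def test_surviving_windows_disjoint_from_genes(self, rng):
        ws = make_windows({"c": 500_000}, size=50_000, step=10_000)
        genes = PeakSet([GenomicInterval("c", int(s), int(s) + 2_000)
                         for s in rng.integers(0, 480_000, 8)])
        out = geneless_windows(ws, genes)
        for w in out:
            assert not any(w.overlaps(g) for g in genes)
        # interval oracle: kept set is exactly the disjoint ones
        expected = [w for w in ws if not any(w.overlaps(g) for g in genes)]
        assert list(out.windows) == expected

    def test_order_insensitive_to_exclusion_ordering(self, rng):
        ws = make_windows({"c": 200_000}, size=20_000, step=20_000)
        genes = [GenomicInterval("c", int(s), int(s) + 1_000)
                 for s in rng.integers(0, 190_000, 6)]
        a = geneless_windows(ws, PeakSet(genes))
        b = geneless_windows(ws, PeakSet(genes[::-1]))
        assert a.windows == b.windows


class TestCountReads:
    def test_secondary_reads_never_counted(self):
        regions = [GenomicInterval("c", 0, 100)]
        reads = [ReadRecord(GenomicInterval("c", 10, 50), 256)]
        stats, _ = count_reads_in_regions(reads, regions)
        assert stats[0].value == 0

    def test_duplicate_reads_counted(self):
        regions = [GenomicInterval("c", 0, 100)]
        reads = [ReadRecord(GenomicInterval("c", 10, 50), 1024)]
        stats, _ = count_reads_in_regions(reads, regions)
        assert stats[0].value == 1

    @pytest.mark.parametrize("flag,counted", [
        (0, True), (4, False), (256, False), (2048, False),
        (1024, True), (16, True), (1, True), (256 | 1024, False),
    ])
    def test_flag_mask_semantics(self, flag, counted):
        regions = [GenomicInterval("c", 0, 100)]
        reads = [ReadRecord(GenomicInterval("c", 10, 50), flag)]
        stats, _ = count_reads_in_regions(reads, regions)
        assert stats[0].value == (1 if counted else 0)

    def test_equals_brute_force_double_loop(self, rng):
        regions = [GenomicInterval("c", int(s), int(s) + 500)
                   for s in rng.integers(0, 50_000, 100)]
        reads = [ReadRecord(GenomicInterval("c", int(s), int(s) + 100),
                            int(f))
                 for s, f in zip(rng.integers(0, 50_000, 1000),
                                 rng.choice([0, 4, 256, 1024, 2048], 1000))]
        stats, median = count_reads_in_regions(reads, regions)
        for r, stat in zip(regions, stats):
            brute = sum(
                1 for read in reads
                if not (read.flags & 2308) and read.interval.overlaps(r)
            )
            assert stat.value == brute
        assert median == lower_median([s.value for s in stats])

    def test_poisson_window_median_in_expected_band(self):
        rng = np.random.default_rng(3)
        n_windows, lam = 1_001, 20
        regions = [GenomicInterval("c", i * 100_000, (i + 1) * 100_000)
                   for i in range(n_windows)]
        reads = []
        for i, n in enumerate(rng.poisson(lam, n_windows)):
            starts = rng.integers(i * 100_000, (i + 1) * 100_000 - 100, n)
            reads.extend(ReadRecord(GenomicInterval("c", int(s), int(s) + 100))
                         for s in starts)
        _, median = count_reads_in_regions(reads, regions)
        assert 15 <= median <= 25

    def test_lower_median_for_even_count(self):
        assert lower_median([1.0, 2.0, 3.0, 4.0]) == 2.0


class TestBinnedCorrelation:
    def test_identical_tracks_perfectly_correlated(self, rng):
        values = rng.poisson(10, 5_000).astype(float)
        t = track(values)
        assert binned_correlation(t, track(values), bin=10) == pytest.approx(1.0)

    def test_scaled_track_high_correlation_after_log1p(self, rng):
        values = rng.uniform(1, 100, 5_000)
        r = binned_correlation(track(values), track(values * 2), bin=10)
        assert r >= 0.99

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(8)
        a = track(rng.poisson(5, 10_000).astype(float))
        b = track(rng.poisson(5, 10_000).astype(float))
        assert abs(binned_correlation(a, b, bin=1)) < 0.05

    def test_insufficient_bins_rejected(self):
        a = track([1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            binned_correlation(a, a, bin=3)
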