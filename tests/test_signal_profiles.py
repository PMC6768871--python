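"""Composite profiles, heatmaps, methylation statistics and the
Mann-Whitney comparison, checked against naive per-base oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from plurevert import signal_profiles as sp
from plurevert.io_formats import CoverageTrack, GenomicInterval, MethylationRecord
from plurevert.peak_dynamics import build_consensus_peaks
from plurevert.io_formats import PeakSummit


def make_peaks(positions):
    return build_consensus_peaks(
        [PeakSummit("chr1", int(p), 1.0, "x") for p in positions]
    )


class TestCompositeProfile:
    def test_uniform_coverage_flat_profile(self):
        track = CoverageTrack(depth={"chr1": np.full(20_000, 4, dtype=int)})
        prof = sp.composite_profile(make_peaks([10_000]), track,
                                    halfwidth=500, bin_bp=10)
        expected = 4 / (track.library_size / 1e6)
        np.testing.assert_allclose(prof.central, expected)
        assert len(prof.offsets) == 100

    def test_triangular_pileup_peaks_at_zero_offset(self):
        depth = np.zeros(20_000, dtype=int)
        for c in (5_000, 12_000):
            for d in range(200):
                depth[c - d] += 200 - d
                depth[c + d] += 200 - d
        track = CoverageTrack(depth={"chr1": depth})
        prof = sp.composite_profile(make_peaks([5_000, 12_000]), track,
                                    halfwidth=400, bin_bp=1)
        mid = len(prof.central) // 2
        assert abs(int(np.argmax(prof.central)) - mid) <= 1
        # symmetric away from the sharp triangle edge
        for d in (50, 100, 150):
            assert prof.central[mid + d] == pytest.approx(
                prof.central[mid - d], rel=0.05
            )

    def test_normalization_invariance(self):
        depth = np.random.default_rng(1).poisson(5, 20_000).astype(np.int64)
        t1 = CoverageTrack(depth={"chr1": depth.copy()})
        t2 = CoverageTrack(depth={"chr1": depth * 3},
                           library_size=t1.library_size * 3)
        peaks = make_peaks([4_000, 9_000])
        p1 = sp.composite_profile(peaks, t1, halfwidth=500)
        p2 = sp.composite_profile(peaks, t2, halfwidth=500)
        np.testing.assert_allclose(p1.central, p2.central, rtol=1e-12)

    def test_matches_naive_binning_oracle(self, rng):
        depth = rng.poisson(3, 30_000).astype(np.int64)
        track = CoverageTrack(depth={"chr1": depth})
        centers = [5_000, 11_000, 17_000]
        prof = sp.composite_profile(make_peaks(centers), track,
                                    halfwidth=200, bin_bp=10)
        per_m = track.library_size / 1e6
        rows = []
        for c in centers:
            vals = [depth[c - 200 + j] for j in range(400)]
            rows.append([np.mean(vals[k * 10:(k + 1) * 10]) / per_m
                         for k in range(40)])
        np.testing.assert_allclose(prof.central, np.median(rows, axis=0),
                                   atol=1e-12)

    def test_empty_peaks_raises(self):
        track = CoverageTrack(depth={"chr1": np.ones(100, dtype=int)})
        with pytest.raises(ValueError):
            sp.composite_profile([], track)


class TestDensityHeatmap:
    def test_shape_and_cap(self, rng):
        depth = rng.poisson(4, 40_000).astype(np.int64)
        track = CoverageTrack(depth={"chr1": depth})
        peaks = make_peaks(np.arange(3_000, 37_000, 1_500))
        (hm,) = sp.density_heatmap([peaks], track)
        assert hm.matrix.shape[1] == 400  # +/- 2 kb at 10 bp
        assert hm.matrix.max() <= hm.cap_value + 1e-12
        # cap equals the pre-cap 99th percentile of the raw matrix
        raw = sp._region_matrix(sp._centers(peaks), track, 2000, 10)
        assert hm.cap_value == pytest.approx(np.quantile(raw, 0.99))
        # monotone below the cap: relative order preserved
        below = raw < hm.cap_value
        np.testing.assert_array_equal(hm.matrix[below], raw[below])

    def test_joint_cap_across_sets(self, rng):
        depth = rng.poisson(4, 40_000).astype(np.int64)
        depth[9_000:9_100] = 500  # outlier only in set A
        track = CoverageTrack(depth={"chr1": depth})
        set_a = make_peaks([9_050])
        set_b = make_peaks([25_000])
        hm_a, hm_b = sp.density_heatmap([set_a, set_b], track,
                                        halfwidth=500)
        assert hm_a.cap_value == hm_b.cap_value


def meth_records(chrom, pos_fracs, coverage=10):
    return [
        MethylationRecord(chrom, p, coverage, int(round(f * coverage)))
        for p, f in pos_fracs
    ]


class TestMethylationComposite:
    def test_fully_methylated_gives_unit_profile(self):
        region = GenomicInterval("chr1", 9_700, 10_300)
        meth = meth_records("chr1", [(10_000 + d, 1.0)
                                     for d in range(-1500, 1501, 100)])
        prof = sp.methylation_composite([region], meth, halfwidth=1500)
        covered = ~np.isnan(prof.central)
        assert covered.any()
        np.testing.assert_allclose(prof.central[covered], 1.0)
        np.testing.assert_allclose(prof.dispersion[covered], 0.0)

    def test_low_coverage_cpg_excluded(self):
        region = GenomicInterval("chr1", 900, 1100)
        meth = [MethylationRecord("chr1", 1000, 2, 2)]
        prof = sp.methylation_composite([region], meth, halfwidth=200)
        assert np.isnan(prof.central).all()

    def test_matches_window_enumeration_oracle(self, rng):
        region = GenomicInterval("chr1", 4_000, 4_600)
        center = region.center
        pos = np.sort(rng.choice(np.arange(center - 2000, center + 2000),
                                 size=120, replace=False))
        cov = rng.poisson(8, 120)
        meths = rng.binomial(cov, 0.4)
        records = [MethylationRecord("chr1", int(p), int(c), int(m))
                   for p, c, m in zip(pos, cov, meths)]
        prof = sp.methylation_composite([region], records)
        for j, w0 in enumerate(range(-2000, 2000 - 100 + 1, 25)):
            fracs = [m / c for p, c, m in zip(pos, cov, meths)
                     if c >= 3 and center + w0 <= p < center + w0 + 100]
            if fracs:
                assert prof.central[j] == pytest.approx(np.mean(fracs),
                                                        abs=1e-12)
            else:
                assert np.isnan(prof.central[j])

    def test_strand_flip_reverses_offsets(self, rng):
        fwd = GenomicInterval("chr1", 4_000, 4_600, "+")
        rev = GenomicInterval("chr1", 4_000, 4_600, "-")
        pos = np.sort(rng.choice(np.arange(2_000, 7_000), size=80,
                                 replace=False))
        records = [MethylationRecord("chr1", int(p), 10,
                                     int(rng.integers(0, 11))) for p in pos]
        pf = sp.methylation_composite([fwd], records)
        pr = sp.methylation_composite([rev], records)
        np.testing.assert_array_equal(pf.central, pr.central[::-1])


class TestBinnedAndRegionMethylation:
    def test_single_cpg_bin(self):
        region = GenomicInterval("chr1", 2_400, 2_600)
        # bin 3 of the 5 kb span starts at center-2500+150
        meth = [MethylationRecord("chr1", 2_500 - 2_500 + 175, 10, 5)]
        mat = sp.binned_methylation([region], meth)
        assert mat.shape == (1, 100)
        assert mat[0, 3] == pytest.approx(0.5)
        assert np.isnan(np.delete(mat[0], 3)).all()

    def test_no_cpgs_all_missing(self):
        mat = sp.binned_methylation([GenomicInterval("chr1", 0, 100)], [])
        assert np.isnan(mat).all()

    def test_agrees_with_composite_at_matching_geometry(self, rng):
        region = GenomicInterval("chr1", 9_000, 9_600)
        pos = np.sort(rng.choice(np.arange(6_000, 13_000), size=150,
                                 replace=False))
        cov = rng.poisson(6, 150)
        meths = rng.binomial(np.maximum(cov, 0), 0.5)
        records = [MethylationRecord("chr1", int(p), int(c), int(m))
                   for p, c, m in zip(pos, cov, meths)]
        # non-overlapping windows: window == slide == bin width
        prof = sp.methylation_composite([region], records, halfwidth=1000,
                                        window=50, slide=50)
        mat = sp.binned_methylation([region], records, span=2000, bin_bp=50)
        np.testing.assert_allclose(prof.central, mat[0], equal_nan=True)

    def test_mean_region_methylation_conventions(self):
        region = GenomicInterval("chr1", 0, 1000)
        none = sp.mean_region_methylation(region, [])
        assert np.isnan(none)
        one = sp.mean_region_methylation(
            region, [MethylationRecord("chr1", 10, 10, 5)]
        )
        assert one == pytest.approx(0.5)
        # unweighted: (3/3 + 0/4)/2 = 0.5 regardless of coverage imbalance
        two = sp.mean_region_methylation(
            region,
            [MethylationRecord("chr1", 10, 3, 3),
             MethylationRecord("chr1", 20, 4, 0)],
        )
        assert two == pytest.approx(0.5)
        weighted = sp.mean_region_methylation(
            region,
            [MethylationRecord("chr1", 10, 3, 3),
             MethylationRecord("chr1", 20, 4, 0)],
            weighted=True,
        )
        assert weighted == pytest.approx(3 / 7)


class TestCpgDensity:
    def test_hand_counts(self):
        genome = {"chr1": "ACGCGTAAAA"}
        dens, summary = sp.cpg_density(
            [GenomicInterval("chr1", 0, 6)], genome
        )
        assert dens[0] == pytest.approx(100 * 2 / 6)
        dens2, _ = sp.cpg_density([GenomicInterval("chr1", 6, 10)], genome)
        assert dens2[0] == 0.0

    def test_boundary_dinucleotide_counted_once(self):
        # CG straddling the interval end: start inside -> counted
        genome = {"chr1": "AAACGAAA"}
        dens, _ = sp.cpg_density([GenomicInterval("chr1", 0, 4)], genome)
        assert dens[0] == pytest.approx(100 / 4)
        dens, _ = sp.cpg_density([GenomicInterval("chr1", 4, 8)], genome)
        assert dens[0] == 0.0

    def test_islands_denser_than_background(self, small_genome):
        genome, islands = small_genome
        island_dens, i_summary = sp.cpg_density(islands, genome)
        tiles = [GenomicInterval("chr1", s, s + 1000)
                 for s in range(0, 200_000, 1000)]
        _, t_summary = sp.cpg_density(tiles, genome)
        assert i_summary["mean"] / t_summary["mean"] > 3

    def test_interval_outside_genome_raises(self):
        with pytest.raises(ValueError):
            sp.cpg_density([GenomicInterval("chr1", 0, 100)], {"chr1": "ACGT"})


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        u, p = sp.compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        u, p = sp.compare_distributions([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_matches_independent_rank_enumeration(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.8, 1, 6)
        u, p = sp.compare_distributions(a, b)
        # oracle: count pairwise wins per assignment (different route from
        # the implementation's midrank sums)
        pooled = np.concatenate([a, b])
        n1 = len(a)

        def u_of(idx):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(len(pooled)) if i not in idx]]
            wins = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            return wins

        us = [u_of(idx) for idx in
              itertools.combinations(range(len(pooled)), n1)]
        u_obs = u_of(tuple(range(n1)))
        n_le = sum(1 for v in us if v <= u_obs + 1e-9)
        n_ge = sum(1 for v in us if v >= u_obs - 1e-9)
        assert u == pytest.approx(u_obs)
        assert p == pytest.approx(min(1.0, 2 * min(n_le, n_ge) / len(us)))

    def test_asymptotic_close_to_exact_at_ten_per_group(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        _, p_exact = sp.compare_distributions(a, b)
        p_asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            sp.compare_distributions([], [1.0])
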