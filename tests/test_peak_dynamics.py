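"""Consensus merging, occupancy RPKM, dynamics classes, Venn and gene
assignment, each checked against brute-force oracles on small instances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plurevert import peak_dynamics as pk
from plurevert.config import COND_0H, COND_48H, COND_96H, COND_DOX, PipelineConfig
from plurevert.io_formats import CoverageTrack, GeneModel, GenomicInterval, PeakSummit


def brute_force_merge(summits):
    """Independent oracle: transitive closure of the |pos diff| <= 1
    relation via union-find, then score-weighted (or plain) means."""
    parent = list(range(len(summits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(summits):
        for j, b in enumerate(summits):
            if a.chrom == b.chrom and abs(a.summit_pos - b.summit_pos) <= 1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(summits)):
        groups.setdefault(find(i), []).append(summits[i])
    out = []
    for members in groups.values():
        w = sum(m.score for m in members)
        if w > 0:
            mean = sum(m.score * m.summit_pos for m in members) / w
        else:
            mean = sum(m.summit_pos for m in members) / len(members)
        rounded = int(np.floor(mean + 0.5))
        out.append((members[0].chrom, rounded))
    return sorted(out)


class TestConsensusMerging:
    def test_single_summit(self, config):
        (peak,) = pk.build_consensus_peaks(
            [PeakSummit("chr1", 1000, 5.0, "0h")], config
        )
        assert peak.summit == 1000
        assert (peak.region.start, peak.region.end) == (700, 1300)

    def test_weighted_average_rounding(self, config):
        # weighted mean (10*1000 + 30*1001)/40 = 1000.75 -> 1001
        (peak,) = pk.build_consensus_peaks(
            [PeakSummit("chr1", 1000, 10.0, "0h"),
             PeakSummit("chr1", 1001, 30.0, "96h")],
            config,
        )
        assert peak.summit == 1001
        assert len(peak.members) == 2

    def test_gap_of_two_does_not_merge(self, config):
        peaks = pk.build_consensus_peaks(
            [PeakSummit("chr1", 1000, 1.0, "a"),
             PeakSummit("chr1", 1002, 1.0, "b")],
            config,
        )
        assert len(peaks) == 2

    def test_all_zero_scores_fall_back_to_plain_mean(self, config):
        (peak,) = pk.build_consensus_peaks(
            [PeakSummit("chr1", 1000, 0.0, "a"),
             PeakSummit("chr1", 1001, 0.0, "b")],
            config,
        )
        assert peak.summit == 1001  # mean 1000.5 rounds half away from zero

    def test_empty_input(self, config):
        assert pk.build_consensus_peaks([], config) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]),
                  st.integers(min_value=0, max_value=300),
                  st.floats(min_value=0, max_value=10)),
        max_size=40,
    ))
    def test_matches_union_find_oracle(self, raw):
        summits = [PeakSummit(c, p, round(s, 3), "x") for c, p, s in raw]
        peaks = pk.build_consensus_peaks(summits)
        got = sorted((p.chrom, p.summit) for p in peaks)
        assert got == brute_force_merge(summits)

    def test_order_invariance_and_idempotence(self, rng, config):
        positions = rng.choice(50_000, size=120, replace=False)
        summits = [
            PeakSummit("chr1", int(p), float(rng.integers(1, 20)), "a")
            for p in positions
        ]
        ref = pk.build_consensus_peaks(summits, config)
        perm = [summits[i] for i in rng.permutation(len(summits))]
        shuffled = pk.build_consensus_peaks(perm, config)
        assert [(p.chrom, p.summit) for p in ref] == \
            [(p.chrom, p.summit) for p in shuffled]
        # idempotence: re-merging the consensus summits changes nothing
        again = pk.build_consensus_peaks(
            [PeakSummit(p.chrom, p.summit, 1.0, "c") for p in ref], config
        )
        assert [(p.chrom, p.summit) for p in again] == \
            [(p.chrom, p.summit) for p in ref]


class TestIntensity:
    def _peak(self, summit=1000):
        return pk.build_consensus_peaks(
            [PeakSummit("chr1", summit, 1.0, "0h")]
        )

    def test_zero_coverage_gives_zero(self):
        peaks = self._peak()
        track = CoverageTrack(depth={"chr1": np.zeros(5000, dtype=int)},
                              library_size=10_000_000)
        pk.quantify_peak_intensity(peaks, track, COND_0H)
        assert peaks[0].intensity[COND_0H] == 0.0

    def test_rpkm_formula(self):
        # max depth 30, 0.6 kb region, 10 M library -> 30/(0.6*10) = 5 RPKM
        peaks = self._peak()
        depth = np.zeros(5000, dtype=int)
        depth[995:1005] = 30
        track = CoverageTrack(depth={"chr1": depth}, library_size=10_000_000)
        pk.quantify_peak_intensity(peaks, track, COND_0H)
        assert peaks[0].intensity[COND_0H] == pytest.approx(5.0)
        # doubling the library halves the RPKM
        track2 = CoverageTrack(depth={"chr1": depth.copy()},
                               library_size=20_000_000)
        pk.quantify_peak_intensity(peaks, track2, COND_0H)
        assert peaks[0].intensity[COND_0H] == pytest.approx(2.5)

    def test_matches_per_base_max_oracle(self, rng):
        depth = rng.poisson(3.0, size=60_000).astype(np.int64)
        track = CoverageTrack(depth={"chr1": depth})
        positions = rng.choice(np.arange(1000, 59_000), size=50,
                               replace=False)
        summits = [PeakSummit("chr1", int(p), 1.0, "0h")
                   for p in sorted(positions)]
        peaks = pk.build_consensus_peaks(summits)
        pk.quantify_peak_intensity(peaks, track, COND_0H)
        for p in peaks:
            expected = max(depth[i] for i in range(p.region.start,
                                                   p.region.end))
            expected /= 0.6 * track.library_size / 1e6
            assert p.intensity[COND_0H] == pytest.approx(expected)

    def test_region_clipped_at_chromosome_end(self):
        peaks = self._peak(summit=4990)
        track = CoverageTrack(depth={"chr1": np.full(5000, 6, dtype=int)})
        pk.quantify_peak_intensity(peaks, track, COND_0H)
        assert peaks[0].intensity[COND_0H] > 0


class TestDynamicAndClassification:
    def _peak_with(self, i0, i48, i96, idox=None):
        (p,) = pk.build_consensus_peaks([PeakSummit("chr1", 1000, 1.0, "x")])
        p.intensity = {COND_0H: i0, COND_48H: i48, COND_96H: i96}
        if idox is not None:
            p.intensity[COND_DOX] = idox
        return p

    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ((3, 3, 3), False),
            ((6.1, 3, 2.9), True),  # (6.2)/(3.0) ~ 2.07 with pseudocount
            ((3.9, 2.0, 1.9), True),  # ratio exactly 2.0: inclusive
        ],
    )
    def test_dynamic_call(self, intensities, expected):
        p = self._peak_with(*intensities)
        pk.call_dynamic_peaks([p])
        assert p.is_dynamic is expected

    def test_missing_condition_raises(self):
        p = self._peak_with(1, 1, 1)
        del p.intensity[COND_96H]
        with pytest.raises(KeyError, match="96h"):
            pk.call_dynamic_peaks([p])

    @pytest.mark.parametrize(
        "i0,i96,idox,expected",
        [
            (5, 1, 4, pk.PLURI_REACCESSED),
            (5, 1, 1, pk.PLURI_EXCLUSIVE),
            (5, 1, None, pk.PLURI_OTHER),
            (1, 5, 5, pk.DIFFERENTIATION),
            (5, 5, 1, pk.STATIC_BOUND),
            (1, 1, 5, pk.STATIC_UNBOUND),
            (3, 1, 3, pk.PLURI_REACCESSED),  # threshold inclusive
        ],
    )
    def test_class_rules(self, i0, i96, idox, expected):
        p = self._peak_with(i0, 0, i96, idox)
        pk.classify_peak_dynamics([p])
        assert p.label == expected

    def test_classes_partition(self, rng):
        peaks = []
        for i in range(60):
            p = self._peak_with(*rng.uniform(0, 8, size=3),
                                rng.uniform(0, 8))
            peaks.append(p)
        by_class = pk.classify_peak_dynamics(peaks)
        assert sum(len(v) for v in by_class.values()) == len(peaks)
        assert all(p.label is not None for p in peaks)


class TestVenn:
    def test_hand_example(self):
        counts = pk.venn_counts({"A": {"1", "2"}, "B": {"2", "3"},
                                 "C": {"3"}})
        assert counts[("A",)] == 1
        assert counts[("A", "B")] == 1
        assert counts[("B", "C")] == 1
        assert sum(counts.values()) == 3

    def test_identical_sets_all_in_triple_overlap(self):
        s = {"a", "b", "c"}
        counts = pk.venn_counts({"X": s, "Y": set(s), "Z": set(s)})
        assert counts[("X", "Y", "Z")] == 3
        assert sum(counts.values()) == 3

    def test_empty_sets(self):
        counts = pk.venn_counts({"A": set(), "B": set(), "C": set()})
        assert all(v == 0 for v in counts.values())

    def test_random_matches_enumeration(self, rng):
        universe = [str(i) for i in range(30)]
        sets = {n: set(rng.choice(universe, size=rng.integers(0, 20),
                                  replace=False))
                for n in "ABC"}
        counts = pk.venn_counts(sets)
        for item in set().union(*sets.values()):
            membership = tuple(sorted(n for n in "ABC" if item in sets[n]))
            assert counts[membership] >= 1
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            pk.venn_counts({"A": {"1"}, "B": set(), "C": set()},
                           universe={"2"})


class TestGeneAssignment:
    def test_summit_at_tss(self):
        (p,) = pk.build_consensus_peaks([PeakSummit("chr1", 500, 1.0, "x")])
        genes = [GeneModel("g1", "chr1", "+", 500)]
        out = pk.assign_nearest_gene([p], genes)
        assert out[p.peak_id].gene_id == "g1"
        assert out[p.peak_id].distance_bp == 0

    def test_tie_breaks_to_smaller_gene_id(self):
        (p,) = pk.build_consensus_peaks([PeakSummit("chr1", 500, 1.0, "x")])
        genes = [GeneModel("gB", "chr1", "+", 400),
                 GeneModel("gA", "chr1", "-", 600)]
        out = pk.assign_nearest_gene([p], genes)
        assert out[p.peak_id].gene_id == "gA"

    def test_non_coding_ignored_and_empty_raises(self):
        (p,) = pk.build_consensus_peaks([PeakSummit("chr1", 500, 1.0, "x")])
        genes = [GeneModel("nc", "chr1", "+", 500, "other"),
                 GeneModel("pc", "chr1", "+", 9000)]
        out = pk.assign_nearest_gene([p], genes)
        assert out[p.peak_id].gene_id == "pc"
        with pytest.raises(ValueError):
            pk.assign_nearest_gene([p], [genes[0]])

    def test_matches_exhaustive_scan(self, rng):
        summits = sorted(rng.choice(100_000, size=50, replace=False))
        peaks = pk.build_consensus_peaks(
            [PeakSummit("chr1", int(s), 1.0, "x") for s in summits]
        )
        genes = [GeneModel(f"g{i:03d}", "chr1", "+",
                           int(rng.integers(0, 100_000)))
                 for i in range(40)]
        out = pk.assign_nearest_gene(peaks, genes)
        for p in peaks:
            best = min(genes, key=lambda g: (abs(g.tss - p.summit),
                                             g.gene_id))
            assert out[p.peak_id].gene_id == best.gene_id


class TestAnnotateFeatures:
    def test_cgi_edge_overlap_and_tss_boundary(self):
        (p,) = pk.build_consensus_peaks([PeakSummit("chr1", 1000, 1.0, "x")])
        # region [700, 1300); island ending at 701 shares exactly one base
        islands = [GenomicInterval("chr1", 600, 701)]
        flags = pk.annotate_features([p], [("chr1", 3001)], islands)
        assert flags[p.peak_id]["cgi_overlap"] is True
        assert flags[p.peak_id]["tss_proximal"] is False  # 2001 bp away
        flags = pk.annotate_features([p], [("chr1", 2999)], islands)
        assert flags[p.peak_id]["tss_proximal"] is True

    def test_matches_brute_force(self, rng):
        summits = sorted(rng.choice(50_000, size=40, replace=False))
        peaks = pk.build_consensus_peaks(
            [PeakSummit("chr1", int(s), 1.0, "x") for s in summits]
        )
        islands = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 900)))
            for s in rng.choice(49_000, size=10, replace=False)
        ]
        tss = [("chr1", int(t)) for t in rng.choice(50_000, size=15,
                                                    replace=False)]
        flags = pk.annotate_features(peaks, tss, islands)
        for p in peaks:
            cgi = any(iv.start < p.region.end and p.region.start < iv.end
                      for iv in islands)
            prox = any(abs(t - p.summit) < 2000 for _, t in tss)
            assert flags[p.peak_id]["cgi_overlap"] == cgi
            assert flags[p.peak_id]["tss_proximal"] == prox
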