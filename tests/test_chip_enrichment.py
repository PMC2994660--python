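"""Hybrid-genome coverage, window medians, and IP/Input enrichment."""

import numpy as np
import pytest

from coevoscan import (CoverageTrack, GenomeRegion, SimSpecChip,
                       concat_hybrid_genome, coverage_from_fragments,
                       per_base_ratio, region_enrichment,
                       simulate_chip_experiment, window_correlation,
                       window_medians)


class TestConcatHybridGenome:
    def test_order_and_prefixing(self):
        a = {"chrI": "ACGT", "chrII": "GGCC"}
        b = {"chrI": "TTTT", "chrII": "AAAA", "chrIII": "CGCG"}
        hybrid, manifest = concat_hybrid_genome(a, b, "Sc_", "Sb_")
        assert list(hybrid) == ["Sc_chrI", "Sc_chrII", "Sb_chrI",
                                "Sb_chrII", "Sb_chrIII"]
        assert hybrid["Sb_chrI"] == "TTTT"

    def test_empty_second_genome(self):
        a = {"chrI": "ACGT"}
        hybrid, _ = concat_hybrid_genome(a, {}, "Sc_", "Sb_")
        assert hybrid == {"Sc_chrI": "ACGT"}

    def test_manifest_partitions_contigs(self):
        a = {"chrI": "ACGT"}
        b = {"chrI": "TT", "chrII": "GG"}
        hybrid, manifest = concat_hybrid_genome(a, b, "Sc_", "Sb_")
        assert set(manifest["contig"]) == set(hybrid)
        assert (manifest["source"] == "a").sum() == 1
        assert (manifest["source"] == "b").sum() == 2

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            concat_hybrid_genome({"x": "AC"}, {"x": "GT"}, "", "")


class TestCoverage:
    def test_single_fragment(self):
        tracks = coverage_from_fragments([("c", 2, 5)], {"c": 8})
        assert tracks["c"].counts.tolist() == [0, 0, 1, 1, 1, 0, 0, 0]

    def test_additivity(self):
        frags = [("c", 2, 5), ("c", 2, 5)]
        tracks = coverage_from_fragments(frags, {"c": 8})
        assert tracks["c"].counts.tolist() == [0, 0, 2, 2, 2, 0, 0, 0]

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(2)
        L = 200
        frags = []
        for _ in range(100):
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, L + 1))
            frags.append(("c", s, e))
        counts = coverage_from_fragments(frags, {"c": L})["c"].counts
        oracle = np.array([sum(s <= b < e for _, s, e in frags)
                           for b in range(L)])
        assert np.array_equal(counts, oracle)

    def test_conservation(self):
        rng = np.random.default_rng(3)
        frags = [("c", int(s), int(s) + 10)
                 for s in rng.integers(0, 90, size=50)]
        counts = coverage_from_fragments(frags, {"c": 100})["c"].counts
        assert counts.sum() == sum(e - s for _, s, e in frags)

    def test_out_of_bounds_reported_with_index(self):
        with pytest.raises(ValueError, match="fragment 1"):
            coverage_from_fragments([("c", 0, 5), ("c", 6, 12)], {"c": 10})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CoverageTrack("c", np.array([1, -1]))


class TestWindowMedians:
    def test_constant_track(self):
        track = CoverageTrack("c", np.full(400, 7))
        wm = window_medians(track)
        assert np.all(wm.medians == 7)

    def test_window_grid_and_trailing_rule(self):
        wm = window_medians(CoverageTrack("c", np.arange(250)))
        assert wm.starts.tolist() == [0, 50, 100, 150]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 50, size=730)
        wm = window_medians(CoverageTrack("c", counts))
        for s, m in zip(wm.starts, wm.medians):
            w = np.sort(counts[s:s + 100])
            assert m == (w[49] + w[50]) / 2.0

    def test_short_contig_warns_empty(self):
        with pytest.warns(UserWarning):
            wm = window_medians(CoverageTrack("c", np.arange(40)))
        assert len(wm.starts) == 0

    def test_shift_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=300)
        base = window_medians(CoverageTrack("c", counts))
        shifted = window_medians(CoverageTrack("c", counts + 11))
        assert np.allclose(shifted.medians - 11, base.medians)
        bigger = window_medians(CoverageTrack("c", counts + rng.integers(
            0, 5, size=300)))
        assert np.all(bigger.medians >= base.medians)


class TestPerBaseRatio:
    def test_constant_ratio(self):
        ip = CoverageTrack("c", np.full(50, 20))
        inp = CoverageTrack("c", np.full(50, 10))
        ratio, masked = per_base_ratio(ip, inp)
        assert np.all(ratio == 2.0) and masked == 0.0

    def test_zero_input_masks_base(self):
        ip = CoverageTrack("c", np.array([4, 4, 4]))
        inp = CoverageTrack("c", np.array([2, 0, 2]))
        ratio, masked = per_base_ratio(ip, inp)
        assert np.isnan(ratio[1]) and ratio[0] == 2.0
        assert masked == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_base_ratio(CoverageTrack("c", np.ones(3)),
                           CoverageTrack("c", np.ones(4)))


def _uniform_experiment(ip_level, input_level, L=6000):
    ip = CoverageTrack("c", np.full(L, ip_level))
    inp = CoverageTrack("c", np.full(L, input_level))
    return window_medians(ip), window_medians(inp)


class TestRegionEnrichment:
    def test_uniform_tracks_give_depth_ratio_and_unit_norm(self):
        ip_w, in_w = _uniform_experiment(12, 30)
        regions = [GenomeRegion("c", 1000, 1600, "query"),
                   GenomeRegion("c", 4000, 4600, "ctrl", "control")]
        out = region_enrichment(ip_w, in_w, regions, regions[1])
        assert out[0].mean_ratio == pytest.approx(0.4)
        assert out[0].normalized_ratio == pytest.approx(1.0)

    def test_control_against_itself_is_one(self):
        ip_w, in_w = _uniform_experiment(12, 30)
        ctrl = GenomeRegion("c", 4000, 4600, "ctrl", "control")
        out = region_enrichment(ip_w, in_w, [ctrl], ctrl)
        assert out[0].normalized_ratio == 1.0

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        counts_ip = rng.integers(5, 40, size=6000)
        counts_in = rng.integers(20, 60, size=6000)
        regions = [GenomeRegion("c", 1000, 1600, "q"),
                   GenomeRegion("c", 4000, 4600, "ctrl", "control")]

        def norm(scale):
            ip_w = window_medians(CoverageTrack("c", counts_ip * scale))
            in_w = window_medians(CoverageTrack("c", counts_in * scale))
            return region_enrichment(ip_w, in_w, regions,
                                     regions[1])[0].normalized_ratio

        assert norm(1) == pytest.approx(norm(3))

    def test_non_600bp_region_warns(self):
        ip_w, in_w = _uniform_experiment(12, 30)
        regions = [GenomeRegion("c", 1000, 1500, "short"),
                   GenomeRegion("c", 4000, 4600, "ctrl", "control")]
        with pytest.warns(UserWarning, match="not 600"):
            region_enrichment(ip_w, in_w, regions, regions[1])

    def test_region_without_windows_rejected(self):
        ip_w, in_w = _uniform_experiment(12, 30)
        far = GenomeRegion("d", 0, 600, "offcontig")
        ctrl = GenomeRegion("c", 4000, 4600, "ctrl", "control")
        with pytest.raises(ValueError):
            region_enrichment(ip_w, in_w, [far], ctrl)


class TestWindowCorrelation:
    def test_identical_tracks(self):
        rng = np.random.default_rng(7)
        t = CoverageTrack("c", rng.integers(0, 40, size=2000))
        wm = window_medians(t)
        assert window_correlation(wm, wm) == pytest.approx(1.0)

    def test_negation_around_mean(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(10, 40, size=2000).astype(float)
        a = window_medians(CoverageTrack("c", counts))
        flipped = 2 * counts.mean() - counts
        b = window_medians(CoverageTrack("c", flipped))
        # medians are not exactly linear, so allow slight departure
        assert window_correlation(a, b) < -0.95

    def test_zero_variance_rejected(self):
        wm = window_medians(CoverageTrack("c", np.full(1000, 5)))
        with pytest.raises(ValueError, match="variance"):
            window_correlation(wm, wm)

    def test_replicates_of_same_experiment_correlate(self):
        regions = [("c", 3000, 3600, 14.0, "X"),
                   ("c", 9000, 9600, 18.6, "HMR-E")]
        specs = [SimSpecChip({"c": 20000}, mu=25.0, s=0.4, regions=regions,
                             seed=s) for s in (10, 11)]
        wms = []
        for spec in specs:
            ip, _, _ = simulate_chip_experiment(spec)
            wms.append({c: window_medians(t) for c, t in ip.items()})
        assert window_correlation(*wms) >= 0.9
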