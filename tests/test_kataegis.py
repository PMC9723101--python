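"""Rainfall distances, kataegis calling, and SV-high/low distance comparison."""

import math

import numpy as np
import pytest

from svecho.binning import bin_counts, moving_average
from svecho.io import GenomeAssembly
from svecho.kataegis import (
    call_kataegis,
    classify_bins_by_sv,
    compare_distances_by_region,
    inter_snv_distances,
    stratify_by_base_pair,
)

from conftest import make_snvs, make_svs


class TestInterSnvDistances:
    def test_pairwise_subtraction_and_zones(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [100, 300, 1300]})
        pts = inter_snv_distances(snvs)
        assert [p.dist_to_prev for p in pts] == [None, 200, 1000]
        assert [p.zone for p in pts] == [None, "lt_1kb", "kb_1_to_Mb_1"]

    def test_single_snv_no_distance(self, tiny_assembly):
        pts = inter_snv_distances(make_snvs(tiny_assembly, {"chr1": [42]}))
        assert len(pts) == 1 and pts[0].dist_to_prev is None

    def test_no_cross_chromosome_distance(self, tiny_assembly):
        pts = inter_snv_distances(make_snvs(tiny_assembly, {"chr1": [100], "chr2": [200]}))
        assert all(p.dist_to_prev is None for p in pts)

    def test_duplicate_positions_flagged_as_ties(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [5, 5]}, ref="A", alt="T")
        pts = inter_snv_distances(snvs)
        assert pts[1].dist_to_prev == 0 and pts[1].is_tie

    def test_empty_input(self, tiny_assembly):
        assert inter_snv_distances(make_snvs(tiny_assembly, {})) == []

    def test_ge_1mb_zone(self, tiny_assembly):
        pts = inter_snv_distances(make_snvs(tiny_assembly, {"chr1": [0, 1_000_000]}))
        assert pts[1].zone == "ge_1Mb"


def kataegis_oracle(positions, max_gap, min_count):
    """Exhaustive chain-rule oracle: maximal runs checked pair by pair."""
    clusters = []
    pos = sorted(positions)
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[j] <= max_gap:
            j += 1
        if j - i + 1 >= min_count:
            clusters.append((pos[i], pos[j], j - i + 1))
        i = j + 1
    return clusters


class TestCallKataegis:
    def test_three_within_chain(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [100, 600, 1050]})
        (c,) = call_kataegis(snvs)
        assert (c.start_pos, c.end_pos, c.n_snvs) == (100, 1050, 3)

    def test_large_gaps_no_cluster(self, tiny_assembly):
        assert call_kataegis(make_snvs(tiny_assembly, {"chr1": [100, 1200, 2300]})) == []

    def test_two_separate_clusters(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [0, 500, 1000, 5000, 5500, 6000]})
        clusters = call_kataegis(snvs)
        assert [(c.start_pos, c.end_pos, c.n_snvs) for c in clusters] == [
            (0, 1000, 3),
            (5000, 6000, 3),
        ]

    def test_invalid_parameters(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {})
        with pytest.raises(ValueError):
            call_kataegis(snvs, max_gap=0)
        with pytest.raises(ValueError):
            call_kataegis(snvs, min_count=1)

    def test_matches_exhaustive_oracle(self, tiny_assembly):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(0, 80))
            pos = sorted(int(p) for p in rng.integers(0, 50_000, n))
            snvs = make_snvs(tiny_assembly, {"chr1": pos})
            max_gap = int(rng.integers(1, 3_000))
            min_count = int(rng.integers(2, 5))
            got = [(c.start_pos, c.end_pos, c.n_snvs)
                   for c in call_kataegis(snvs, max_gap, min_count)]
            assert got == kataegis_oracle(pos, max_gap, min_count)

    def test_clusters_unmergeable_and_disjoint(self, tiny_assembly):
        rng = np.random.default_rng(21)
        pos = sorted(int(p) for p in rng.integers(0, 100_000, 150))
        clusters = call_kataegis(make_snvs(tiny_assembly, {"chr1": pos}), 800, 3)
        for a, b in zip(clusters, clusters[1:]):
            assert b.start_pos - a.end_pos > 800  # not extendable into each other

    def test_window_rule_stricter_than_chain(self, tiny_assembly):
        # chain rule links [0, 900, 1800] (gaps 900); no 1 kb window holds all 3
        snvs = make_snvs(tiny_assembly, {"chr1": [0, 900, 1800]})
        assert len(call_kataegis(snvs, rule="chain")) == 1
        assert call_kataegis(snvs, rule="window") == []

    def test_window_rule_finds_dense_window(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [0, 400, 800]})
        (c,) = call_kataegis(snvs, rule="window")
        assert (c.start_pos, c.end_pos, c.n_snvs) == (0, 800, 3)


class TestClassifyBins:
    def _smoothed(self, values):
        asm = GenomeAssembly((("c", len(values) * 10),))
        from svecho.binning import BinnedTrack

        return BinnedTrack(asm, 10, {"c": np.asarray(values, dtype=float)})

    def test_flat_track_all_low(self):
        labels = classify_bins_by_sv(self._smoothed([2, 2, 2]), 2.0)
        assert not labels["c"].any()

    def test_threshold_arithmetic(self):
        labels = classify_bins_by_sv(self._smoothed([0, 10, 0]), 2.0)
        assert labels["c"].tolist() == [False, True, False]

    def test_fold_one_flat_all_high(self):
        labels = classify_bins_by_sv(self._smoothed([3, 3, 3]), 1.0)
        assert labels["c"].all()


class TestCompareDistances:
    def _setup(self, tiny_assembly, high_positions, low_positions):
        snvs = make_snvs(
            tiny_assembly, {"chr1": sorted(high_positions + low_positions)}
        )
        points = inter_snv_distances(snvs)
        labels = {
            "chr1": np.arange(10) < 5,  # bins 0-4 high, 5-9 low (1 Mb bins)
            "chr2": np.zeros(5, dtype=bool),
        }
        return points, labels

    def test_matches_textbook_welch_on_log_distances(self, tiny_assembly):
        # dense SNVs in "high" half, sparse in "low" half
        high = list(range(100, 2000, 150))
        low = list(range(6_000_000, 9_000_000, 400_000))
        points, labels = self._setup(tiny_assembly, high, low)
        test, desc = compare_distances_by_region(points, labels, 1_000_000)
        a = [math.log10(p.dist_to_prev) for p in points
             if p.dist_to_prev and p.pos < 5_000_000]
        b = [math.log10(p.dist_to_prev) for p in points
             if p.dist_to_prev and p.pos >= 5_000_000]
        na, nb = len(a), len(b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t_ref = (ma - mb) / math.sqrt(va / na + vb / nb)
        assert test.statistic == pytest.approx(t_ref, abs=1e-9)
        assert desc["sv_high"]["mean"] < desc["sv_low"]["mean"]

    def test_exclude_kataegis_drops_cluster_points(self, tiny_assembly):
        high = [100, 200, 300, 400, 2_000_000, 2_600_000]  # cluster at start
        low = list(range(6_000_000, 9_500_000, 350_000))
        points, labels = self._setup(tiny_assembly, high, low)
        snvs = make_snvs(tiny_assembly, {"chr1": sorted(high + low)})
        clusters = call_kataegis(snvs)
        assert clusters, "test setup should plant a cluster"
        _, desc_all = compare_distances_by_region(points, labels, 1_000_000)
        _, desc_excl = compare_distances_by_region(
            points, labels, 1_000_000, exclude_kataegis=True, clusters=clusters
        )
        assert desc_excl["sv_high"]["n"] < desc_all["sv_high"]["n"]

    def test_small_group_rejected(self, tiny_assembly):
        points, labels = self._setup(tiny_assembly, [100, 200], [])
        with pytest.raises(ValueError):
            compare_distances_by_region(points, labels, 1_000_000)


class TestStratifyByBasePair:
    def test_tally(self, tiny_assembly):
        from svecho.io import SnvRecord, SnvSet

        refs = ["A", "T", "G", "C", "A"]
        snvs = SnvSet(
            tiny_assembly,
            [SnvRecord("chr1", 10 + i, r, "G" if r != "G" else "A") for i, r in enumerate(refs)],
        )
        assert stratify_by_base_pair(snvs) == {"AT": 3, "GC": 2}

    def test_empty(self, tiny_assembly):
        assert stratify_by_base_pair(make_snvs(tiny_assembly, {})) == {"AT": 0, "GC": 0}

    def test_all_gc(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": list(range(5))}, ref="G", alt="A")
        counts = stratify_by_base_pair(snvs)
        assert counts == {"AT": 0, "GC": 5}
        assert sum(counts.values()) == len(snvs)
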