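"""Observed/expected SV-proximal SNV counting and the cohort enrichment test."""

import math

import numpy as np
import pytest

from svecho.io import GenomeAssembly
from svecho.proximity import (
    CohortEnrichment,
    EnrichmentResult,
    cohort_enrichment_test,
    enrichment_for_sample,
    expected_snv_count,
    merged_window_length,
    observed_snv_near_sv,
    region_tallies,
    relative_rate,
)

from conftest import make_snvs, make_svs, random_snvs


class TestExpectedSnvCount:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((3000, 3e9, 100, 1e6), 200.0),
            ((5000, 3e9, 0, 1e6), 0.0),
            ((1000, 1e8, 5, 1e4), 1.0),
        ],
    )
    def test_direct_evaluation(self, args, expected):
        assert expected_snv_count(*args) == pytest.approx(expected)

    def test_linearity_in_each_argument(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_snv, n_sv = rng.integers(1, 10_000, 2)
            L = float(rng.integers(10**6, 10**10))
            r = float(rng.integers(1, 10**7))
            base = expected_snv_count(n_snv, L, n_sv, r)
            assert expected_snv_count(2 * n_snv, L, n_sv, r) == pytest.approx(2 * base)
            assert expected_snv_count(n_snv, L, 3 * n_sv, r) == pytest.approx(3 * base)
            assert expected_snv_count(n_snv, L, n_sv, 5 * r) == pytest.approx(5 * base)

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            expected_snv_count(10, 0, 1, 100)


def brute_force_observed(snv_pos: dict, bp_pos: dict, range_bp: int) -> int:
    """O(n·m) double loop (vectorized): distinct SNVs within range of any breakpoint."""
    count = 0
    for chrom, pos in snv_pos.items():
        bps = np.asarray(bp_pos.get(chrom, []), dtype=np.int64)
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size == 0 or bps.size == 0:
            continue
        dist = np.abs(pos[:, None] - bps[None, :]).min(axis=1)
        count += int((dist <= range_bp).sum())
    return count


class TestObservedNearSv:
    def test_linear_scan_example(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [10, 500_000, 2_000_000]})
        svs = make_svs(tiny_assembly, [("chr1", 100_000, "chr1", 100_500)])
        assert observed_snv_near_sv(snvs, svs, 1_000_000) == 2

    def test_different_chromosome_zero(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr2": [100]})
        svs = make_svs(tiny_assembly, [("chr1", 100_000, "chr1", 200_000)])
        assert observed_snv_near_sv(snvs, svs, 1_000_000) == 0

    def test_dedup_across_overlapping_windows(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [120_000]})
        svs = make_svs(tiny_assembly, [("chr1", 100_000, "chr1", 150_000)])
        assert observed_snv_near_sv(snvs, svs, 1_000_000) == 1

    def test_inclusive_boundary(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [1_100_000, 1_100_001]})
        svs = make_svs(tiny_assembly, [("chr1", 100_000, "chr2", 0)])
        assert observed_snv_near_sv(snvs, svs, 1_000_000) == 1

    def test_monotone_in_range(self, tiny_assembly):
        rng = np.random.default_rng(5)
        snvs = random_snvs(rng, tiny_assembly, 300)
        svs = make_svs(tiny_assembly, [("chr1", int(p), "chr1", int(p) + 10)
                                       for p in rng.integers(0, 9_000_000, 5)])
        counts = [observed_snv_near_sv(snvs, svs, r)
                  for r in [0, 10**3, 10**5, 10**6, 10**7]]
        assert counts == sorted(counts)
        # at full range every SNV on a breakpoint-carrying chromosome is counted
        assert counts[-1] == len(snvs.positions("chr1"))

    def test_matches_brute_force_on_random_instances(self, tiny_assembly):
        rng = np.random.default_rng(9)
        for _ in range(50):
            snvs = random_snvs(rng, tiny_assembly, int(rng.integers(0, 400)))
            bps = []
            for _ in range(int(rng.integers(0, 10))):
                c = "chr1" if rng.random() < 0.5 else "chr2"
                L = tiny_assembly.length_of(c)
                bps.append((c, int(rng.integers(0, L)), c, int(rng.integers(0, L))))
            svs = make_svs(tiny_assembly, bps)
            r = int(rng.integers(0, 2_000_000))
            snv_pos = {c: snvs.positions(c) for c in tiny_assembly.names}
            bp_pos = {c: svs.breakpoints(c) for c in tiny_assembly.names}
            assert observed_snv_near_sv(snvs, svs, r) == brute_force_observed(snv_pos, bp_pos, r)


class TestMergedWindowLength:
    def test_disjoint_and_overlapping(self, tiny_assembly):
        svs = make_svs(tiny_assembly, [("chr1", 2_000_000, "chr1", 2_500_000)])
        # windows [1M, 3M+1) and [1.5M, 3.5M+1) merge into [1M, 3.5M+1)
        assert merged_window_length(svs, 1_000_000) == 2_500_001

    def test_clipped_at_chromosome_edges(self, tiny_assembly):
        svs = make_svs(tiny_assembly, [("chr2", 0, "chr2", 4_999_999)])
        assert merged_window_length(svs, 3_000_000) == 5_000_000


class TestRelativeRate:
    @pytest.mark.parametrize("obs,exp,want", [(200, 100, 2.0), (100, 100, 1.0), (0, 50, 0.0)])
    def test_ratio(self, obs, exp, want):
        assert relative_rate(obs, exp) == want

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            relative_rate(5, 0)


def _fake_result(sid, obs, exp, n_snv=1000):
    return EnrichmentResult(
        sample_id=sid, range_bp=10**6, n_snv_total=n_snv, n_sv_total=10,
        observed_near=obs, expected_near=float(exp), expected_corrected=float(exp),
        merged_window_bp=10**6,
    )


class TestCohortEnrichmentTest:
    def test_identical_pairs_degenerate(self):
        results = [_fake_result(f"s{i}", 100, 100) for i in range(5)]
        t = cohort_enrichment_test(results, "paired_counts")
        assert t.statistic == 0.0 and t.p_two_sided == 1.0 and t.degenerate

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(2)
        obs = rng.integers(100, 200, 10)
        exp = obs - rng.integers(1, 30, 10)
        results = [_fake_result(f"s{i}", int(o), float(e)) for i, (o, e) in enumerate(zip(obs, exp))]
        t = cohort_enrichment_test(results, "paired_counts")
        d = obs - exp
        tt = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(tt), len(d) - 1)
        assert t.statistic == pytest.approx(tt, abs=1e-9)
        assert t.p_two_sided == pytest.approx(p, abs=1e-9)

    def test_log_ratio_mode(self):
        results = [_fake_result(f"s{i}", o, 100.0) for i, o in enumerate([150, 180, 130, 200])]
        t = cohort_enrichment_test(results, "log_ratio")
        ratios = np.log(np.array([150, 180, 130, 200]) / 100.0)
        tt = ratios.mean() / (ratios.std(ddof=1) / math.sqrt(4))
        assert t.statistic == pytest.approx(tt, abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cohort_enrichment_test([_fake_result("a", 1, 1.0), _fake_result("b", 1, 1.0)])


class TestRegionTallies:
    def test_membership_and_breakpoints(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [1500]})
        svs = make_svs(tiny_assembly, [("chr1", 1999, "chr2", 3000)])
        (tally,) = region_tallies([("g", ("chr1", 1000, 2000))], snvs, svs)
        assert (tally.n_snv, tally.n_sv_breakpoints, tally.has_both) == (1, 1, True)

    def test_half_open_end_excluded(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {})
        svs = make_svs(tiny_assembly, [("chr1", 2000, "chr2", 3000)])
        (tally,) = region_tallies([("g", ("chr1", 1000, 2000))], snvs, svs)
        assert tally.n_sv_breakpoints == 0 and not tally.has_both

    def test_empty_region_list(self, tiny_assembly):
        assert region_tallies([], make_snvs(tiny_assembly, {}), make_svs(tiny_assembly, [])) == []

    def test_flank_extends_interval(self, tiny_assembly):
        snvs = make_snvs(tiny_assembly, {"chr1": [500]})
        svs = make_svs(tiny_assembly, [("chr1", 2500, "chr2", 3000)])
        (plain,) = region_tallies([("g", ("chr1", 1000, 2000))], snvs, svs)
        (flanked,) = region_tallies([("g", ("chr1", 1000, 2000))], snvs, svs, flank_bp=600)
        assert (plain.n_snv, plain.n_sv_breakpoints) == (0, 0)
        assert (flanked.n_snv, flanked.n_sv_breakpoints) == (1, 1)

    def test_invalid_interval(self, tiny_assembly):
        with pytest.raises(ValueError):
            region_tallies([("g", ("chr1", 2000, 1000))],
                           make_snvs(tiny_assembly, {}), make_svs(tiny_assembly, []))


class TestCohortEnrichmentModel:
    def test_fit_and_summary(self, tiny_assembly):
        rng = np.random.default_rng(4)
        samples = {}
        for i in range(4):
            snvs = random_snvs(rng, tiny_assembly, 200)
            svs = make_svs(tiny_assembly, [("chr1", int(p), "chr1", int(p) + 100)
                                           for p in rng.integers(0, 8_000_000, 3)])
            samples[f"s{i}"] = (snvs, svs)
        res = CohortEnrichment(samples, range_bp=500_000).fit()
        assert len(res.per_sample) == 4
        text = res.summary()
        assert "mean relative rate" in text and "two-sided p" in text
        df = res.to_dataframe()
        assert set(df.columns) >= {"observed_near", "expected_near", "relative_rate"}
        assert (df["observed_near"] <= df["n_snv"]).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortEnrichment({})
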