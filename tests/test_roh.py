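"""Sliding-window ROH caller vs brute-force oracle, inclusion matrix
boundaries, homozygosity summaries and enriched-region tables."""

import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import MISSING, ROHSegment
from rohscan.reference import brute_call_segments, brute_window_scan
from rohscan.roh import (
    ROHParams,
    call_segments,
    carrier_percentage,
    froh,
    inclusion_matrix,
    region_frequency,
    summarize,
    window_scan,
)
from rohscan.experiments import _random_instance

from conftest import make_matrix


class TestWindowScan:
    def test_all_heterozygous_nothing_eligible(self):
        calls = np.ones(200, dtype=np.int8)
        assert not window_scan(calls).any()

    def test_all_homozygous_everything_eligible(self):
        calls = np.full(200, 2, dtype=np.int8)
        assert window_scan(calls).all()

    def test_short_chromosome_single_truncated_window(self):
        calls = np.full(30, 0, dtype=np.int8)  # < 50-SNP window
        assert window_scan(calls).all()
        calls[10] = calls[12] = 1  # two hets kill the only window
        assert not window_scan(calls).any()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            calls, pos, params = _random_instance(rng)
            assert np.array_equal(window_scan(calls, params),
                                  brute_window_scan(calls, params))

    def test_threshold_monotonicity(self, rng):
        calls, pos, params = _random_instance(rng)
        lo = window_scan(calls, ROHParams(**{**params.__dict__, "window_threshold": 0.01}))
        hi = window_scan(calls, ROHParams(**{**params.__dict__, "window_threshold": 0.3}))
        assert (lo | hi == lo).all()  # lowering the threshold only adds SNPs


class TestCallSegments:
    def test_fully_homozygous_chromosome_single_segment(self):
        # 300 hom SNPs spanning exactly 2 Mb
        pos = np.linspace(1, 2_000_000, 300).astype(int)
        pos[-1] = 2_000_000
        gm = make_matrix(np.full((1, 300), 2, dtype=np.int8), pos=pos)
        segs = call_segments(gm)
        assert len(segs) == 1
        assert segs[0].n_snps == 300
        assert segs[0].length_kb == 2000.0
        assert segs[0].phet == 0.0

    def test_min_snp_filter(self):
        pos = np.linspace(1, 2_000_000, 90).astype(int)
        gm = make_matrix(np.full((1, 90), 0, dtype=np.int8), pos=pos)
        assert call_segments(gm) == []

    def test_min_kb_monotonicity(self, rng):
        calls, pos, params = _random_instance(rng)
        gm = make_matrix(calls[None, :], pos=pos)
        base = call_segments(gm, params)
        stricter = ROHParams(**{**params.__dict__, "min_kb": params.min_kb * 2})
        assert len(call_segments(gm, stricter)) <= len(base)

    def test_matches_brute_force_oracle(self, rng):
        n_checked = 0
        for _ in range(40):
            calls, pos, params = _random_instance(rng)
            gm = make_matrix(calls[None, :], pos=pos)
            fast = [(s.pos_start, s.pos_end, s.n_snps) for s in call_segments(gm, params)]
            slow = brute_call_segments(calls, pos, params)
            assert fast == slow
            n_checked += len(slow)
        assert n_checked > 0  # the instances must actually produce segments

    def test_gap_split(self):
        # homozygous run with a 1.5 Mb gap in the middle: split into two runs
        pos = np.concatenate([np.arange(150) * 10_000 + 1,
                              np.arange(150) * 10_000 + 3_000_000])
        gm = make_matrix(np.full((1, 300), 2, dtype=np.int8), pos=pos)
        params = ROHParams(min_snp=100, min_kb=1000)
        segs = call_segments(gm, params)
        assert len(segs) == 2
        assert all(s.n_snps == 150 for s in segs)


class TestInclusionMatrix:
    def test_boundary_snps_inside(self):
        variants = pd.DataFrame({
            "chrom": "1", "id": ["a", "b", "c", "d"],
            "pos": [99, 100, 200, 201],
        })
        segs = [ROHSegment("s1", "1", 100, 200, 2)]
        out = inclusion_matrix(segs, variants, ["s1"])
        assert list(out[0]) == [0, 1, 1, 0]

    def test_no_segments_all_zero(self):
        variants = pd.DataFrame({"chrom": "1", "id": ["a"], "pos": [5]})
        assert inclusion_matrix([], variants, ["s1", "s2"]).sum() == 0

    def test_unknown_sample_rejected(self):
        variants = pd.DataFrame({"chrom": "1", "id": ["a"], "pos": [5]})
        with pytest.raises(KeyError, match="ghost"):
            inclusion_matrix([ROHSegment("ghost", "1", 1, 10, 1)], variants, ["s1"])


class TestFroh:
    def test_arithmetic_from_definition(self):
        segs = [ROHSegment("s1", "1", 1, 150_000_000, 1000)]
        out = froh(segs, ["s1", "s2"])
        assert out["s1"] == pytest.approx(0.05)
        assert out["s2"] == 0.0

    def test_cohort_mean_length_scale(self):
        # a 135 Mb total against the 3 Gb autosomal genome is F_ROH 0.045
        segs = [ROHSegment("s1", "1", 1, 135_000_000, 1000)]
        assert froh(segs, ["s1"])["s1"] == pytest.approx(0.045)

    def test_invariant_to_segment_and_sample_order(self, rng):
        segs = [ROHSegment(f"s{i % 3}", str(c), s, s + 2_000_000, 200)
                for i, (c, s) in enumerate(
                    (rng.integers(1, 5), rng.integers(1, 10**8)) for _ in range(20))]
        a = froh(segs, ["s0", "s1", "s2"])
        b = froh(segs[::-1], ["s2", "s1", "s0"])
        for s in ("s0", "s1", "s2"):
            assert a[s] == b[s]


class TestSummaries:
    def test_cohort_classification_percentages(self):
        params = ROHParams()
        samples = [f"s{i}" for i in range(455)]
        segs = []
        for i, s in enumerate(samples):
            if i < 18:
                continue  # no segments
            long = i >= 24  # 18 none, 6 short-only, 431 long
            length = 3_000_000 if long else 1_500_000
            segs.append(ROHSegment(s, "1", 10**6, 10**6 + length - 1, 150))
        summary = summarize(segs, samples, params)
        assert summary.pct_no_roh == 4.0
        assert summary.pct_short_only == 1.3
        assert summary.pct_any_long == 94.7
        assert summary.n_no_roh + summary.n_short_only + summary.n_any_long == 455

    def test_average_count(self):
        samples = [f"s{i}" for i in range(10)]
        segs = [ROHSegment("s0", "1", 1, 2_000_000, 150) for _ in range(5)]
        assert summarize(segs, samples).avg_n_roh == 0.5

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize([], [])


class TestRegionFrequency:
    def test_carrier_percentages(self):
        assert carrier_percentage(96, 455) == 21.1
        assert carrier_percentage(0, 455) == 0.0
        assert carrier_percentage(455, 455) == 100.0

    def test_enriched_region_table(self):
        variants = pd.DataFrame({
            "chrom": ["1"] * 6, "id": [f"v{j}" for j in range(6)],
            "pos": np.arange(1, 7) * 1000,
        })
        incl = np.zeros((10, 6), dtype=np.int8)
        incl[:3, 1:4] = 1   # 30% frequency on SNPs 1-3
        incl[0, 4] = 1      # 10% on SNP 4
        per_snp, regions = region_frequency(incl, variants, thresholds=(0.20,))
        assert per_snp["frequency"].tolist() == [0, 0.3, 0.3, 0.3, 0.1, 0]
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"], row["n_snps"]) == (2000, 4000, 3)
        assert row["n_carriers"] == 3 and row["carrier_pct"] == 30.0

    def test_carrier_rule_any_vs_all_snps(self):
        # a sample covering only part of the region counts under the
        # any-SNP rule but not under a stricter all-SNPs rule
        variants = pd.DataFrame({
            "chrom": ["1"] * 4, "id": list("abcd"), "pos": [1, 2, 3, 4]})
        incl = np.array([
            [1, 1, 1, 1],
            [1, 1, 0, 0],   # partial overlap
            [0, 0, 0, 0],
        ], dtype=np.int8)
        _, regions = region_frequency(incl, variants, thresholds=(0.3,))
        any_rule = regions.iloc[0]["n_carriers"]
        all_rule = int((incl[:, 0:2].min(axis=1) > 0).sum())
        assert any_rule == 2
        # the region here spans SNPs a-b (freq 2/3 ≥ 0.3 only there)... the
        # stricter rule agrees on this fixture for the emitted region
        assert all_rule == 2
        # but on the full 4-SNP span the two rules differ
        assert int((incl.min(axis=1) > 0).sum()) == 1
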