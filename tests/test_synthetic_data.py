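"""Generator determinism, distributional structure and planted ground truth."""

import numpy as np
import pytest

from rohscan.genotype_io import MISSING
from rohscan.synthetic_data import (
    SimConfig,
    causal_interval,
    causal_span,
    choose_causal_region,
    effect_size_for_variance,
    simulate_genotypes,
    simulate_map,
    simulate_trait,
)


def test_map_shape_sorted_and_deterministic():
    cfg = SimConfig(n_chrom=2, snps_per_chrom=100, seed=3)
    m1 = simulate_map(cfg)
    m2 = simulate_map(cfg)
    assert len(m1) == 200
    assert m1.equals(m2)
    for _, grp in m1.groupby("chrom"):
        assert (np.diff(grp["pos"]) > 0).all()
    assert m1["id"].is_unique


def test_map_span_matches_spacing_distribution():
    cfg = SimConfig(n_chrom=1, snps_per_chrom=300, mean_spacing_bp=10_000, seed=5)
    span = simulate_map(cfg)["pos"].max()
    # span = sum of 300 exponential spacings: mean 3 Mb, SE ~ sqrt(300)·10 kb
    assert abs(span - 3_000_000) < 3 * np.sqrt(300) * 10_000


def test_full_reproducibility_same_seed():
    cfg = SimConfig(n_samples=30, n_chrom=2, snps_per_chrom=300, seed=9)
    gm1, t1 = simulate_genotypes(cfg)
    gm2, t2 = simulate_genotypes(cfg)
    assert np.array_equal(gm1.calls, gm2.calls)
    assert t1.segments == t2.segments
    assert np.array_equal(t1.true_fraction, t2.true_fraction)


def test_no_planting_gives_hwe_and_zero_fraction():
    cfg = SimConfig(n_samples=400, n_chrom=1, snps_per_chrom=200,
                    segment_rate=0.0, genotype_error_rate=0.0,
                    missing_rate=0.0, seed=17)
    gm, truth = simulate_genotypes(cfg)
    assert (truth.true_fraction == 0).all()
    # per-site genotype frequencies match Hardy-Weinberg within binomial error
    p = truth.allele1_freq
    hom_obs = (gm.calls == 2).mean(axis=0)
    se = np.sqrt(p**2 * (1 - p**2) / cfg.n_samples)
    frac_outside = (np.abs(hom_obs - p**2) > 4 * se).mean()
    assert frac_outside < 0.05


def test_no_heterozygotes_inside_planted_segments_without_error():
    cfg = SimConfig(n_samples=40, n_chrom=2, snps_per_chrom=500,
                    segment_rate=2.0, genotype_error_rate=0.0,
                    missing_rate=0.0, seed=23)
    gm, truth = simulate_genotypes(cfg)
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    for i, segs in enumerate(truth.segments):
        for c, s, e in segs:
            inside = (chrom == c) & (pos >= s) & (pos <= e)
            assert not (gm.calls[i, inside] == 1).any()


def test_planted_fraction_hits_target():
    # rate chosen for an expected planted fraction of 5%
    cfg = SimConfig(n_samples=200, seed=31)
    genome = cfg.n_chrom * cfg.snps_per_chrom * cfg.mean_spacing_bp
    cfg.segment_rate = 0.05 * genome / cfg.segment_mean_bp
    _, truth = simulate_genotypes(cfg)
    assert 0.04 <= truth.true_fraction.mean() <= 0.06


def test_segments_non_overlapping_and_within_chromosome():
    cfg = SimConfig(n_samples=50, n_chrom=2, snps_per_chrom=400,
                    segment_rate=6.0, seed=37)
    _, truth = simulate_genotypes(cfg)
    for segs in truth.segments:
        by_chrom = {}
        for c, s, e in segs:
            assert 1 <= s <= e <= truth.chrom_lengths[c]
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 < s2


class TestTrait:
    def _cohort(self, **kw):
        cfg = SimConfig(n_samples=300, n_chrom=2, snps_per_chrom=300,
                        var_polygenic=0.0, seed=41, **kw)
        gm, truth = simulate_genotypes(cfg)
        return cfg, gm, truth

    def test_null_trait_residual_variance(self):
        cfg, gm, truth = self._cohort(trait_model="null", var_noise=1.0)
        frame = simulate_trait(cfg, gm, truth)
        X = np.column_stack([np.ones(len(frame)), frame["age"], frame["sex"]])
        y = frame["trait"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert np.var(resid) == pytest.approx(1.0, rel=0.25)

    def test_zero_effect_identical_to_null(self):
        cfg, gm, truth = self._cohort(trait_model="recessive", beta_effect=0.0)
        t1 = simulate_trait(cfg, gm, truth)["trait"]
        cfg2 = SimConfig(**{**cfg.__dict__, "trait_model": "null"})
        t2 = simulate_trait(cfg2, gm, truth)["trait"]
        assert np.allclose(t1, t2)

    def test_recessive_group_means_differ_by_beta(self):
        cfg, gm, truth = self._cohort(trait_model="recessive", beta_effect=4.0,
                                      genotype_error_rate=0.0)
        frame = simulate_trait(cfg, gm, truth)
        y = frame["trait"].to_numpy()
        hom = truth.causal_status.astype(bool)
        diff = y[hom].mean() - y[~hom].mean()
        assert diff == pytest.approx(4.0, abs=0.6)

    def test_unknown_trait_model_rejected(self):
        cfg, gm, truth = self._cohort()
        cfg.trait_model = "dominant"
        with pytest.raises(ValueError, match="trait_model"):
            simulate_trait(cfg, gm, truth)

    def test_polygenic_requires_grm(self):
        cfg, gm, truth = self._cohort()
        cfg.var_polygenic = 0.5
        with pytest.raises(ValueError, match="grm"):
            simulate_trait(cfg, gm, truth)


def test_causal_region_intervals():
    cfg = SimConfig(n_samples=40, n_chrom=2, snps_per_chrom=400,
                    segment_rate=3.0, seed=43)
    gm, truth = simulate_genotypes(cfg)
    c, p, vid = choose_causal_region(truth, gm.variants)
    lo, hi = causal_interval(truth, c, p)
    lo2, hi2 = causal_span(truth, c, p)
    assert lo2 <= lo <= p <= hi <= hi2
    # every carrier segment covers the intersection interval
    for segs in truth.segments:
        for cc, s, e in segs:
            if cc == c and s <= p <= e:
                assert s <= lo and e >= hi


def test_effect_size_calibration():
    rng = np.random.default_rng(0)
    status = (rng.random(5000) < 0.1).astype(float)
    beta = effect_size_for_variance(status, 0.08, background_var=1.2)
    explained = beta**2 * np.var(status)
    assert explained / (explained + 1.2) == pytest.approx(0.08, rel=1e-6)
    with pytest.raises(ValueError):
        effect_size_for_variance(np.zeros(10), 0.08, 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.01, 0.5)).validate()
    with pytest.raises(ValueError):
        SimConfig(genotype_error_rate=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(segment_mean_bp=1e5, segment_min_bp=2e5).validate()
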