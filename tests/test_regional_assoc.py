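"""Mixed-model regional association: REML recovery, OLS limits, the exact
per-SNP refit oracle, clumping and genotype-model encoding/tests."""

import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import MISSING
from rohscan.reference import reml_refit_pvalue
from rohscan.regional_assoc import (
    AssocResult,
    bonferroni_threshold,
    clump,
    encode_genotype,
    filter_for_association,
    fit_null_lmm,
    scan_regional,
)
from rohscan.regional_assoc import test_genotype as genotype_wald
from rohscan.regional_assoc import test_regional as regional_wald

from conftest import make_matrix


def _structured_grm(rng, n_families=50, family_size=10, rel=0.5):
    """Block-diagonal family relatedness: identifiable variance components."""
    n = n_families * family_size
    K = np.eye(n)
    for f in range(n_families):
        s = slice(f * family_size, (f + 1) * family_size)
        K[s, s] = rel
        np.fill_diagonal(K[s, s], 1.0)
    return K


def _draw_trait(rng, K, covs, var_g, var_e, beta_cov):
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    g = np.sqrt(var_g) * (L @ rng.standard_normal(n))
    return covs @ beta_cov + g + rng.normal(0, np.sqrt(var_e), n)


class TestFilterForAssociation:
    def test_zero_roh_sample_dropped(self):
        incl = np.array([[1, 0, 1], [0, 0, 0], [1, 1, 0]], dtype=np.int8)
        filt, kept, cols, rep = filter_for_association(incl, ["a", "b", "c"])
        assert kept == ["a", "c"]
        assert rep.n_samples_removed == 1

    def test_low_frequency_column_dropped(self):
        incl = np.zeros((200, 2), dtype=np.int8)
        incl[:, 0] = 1
        incl[0, 1] = 1  # 0.5% < 1%
        filt, kept, cols, rep = filter_for_association(incl, [f"s{i}" for i in range(200)])
        assert list(cols) == [0]
        assert rep.n_snps_removed == 1

    def test_hand_fixture_counts(self):
        incl = np.zeros((10, 5), dtype=np.int8)
        incl[0:4, 0] = 1          # keeps samples 0-3 in play
        incl[9, 1] = 1            # sample 9 kept via column 1
        incl[0, 2] = 1
        # samples 4-8 have no ROH at all → dropped (5 removed, 5 remain)
        # frequencies on remaining 5: col0 4/5, col1 1/5, col2 1/5, col3 0, col4 0
        filt, kept, cols, rep = filter_for_association(
            incl, [f"s{i}" for i in range(10)])
        assert rep.n_samples_removed == 5
        assert list(cols) == [0, 1, 2]
        assert filt.shape == (5, 3)

    def test_everything_filtered_errors(self):
        incl = np.zeros((5, 3), dtype=np.int8)
        incl[0, 0] = 1
        incl[1, 1] = 1   # both surviving columns at frequency 0.5
        with pytest.raises(ValueError):
            filter_for_association(incl, list("abcde"), freq_min=0.9)


class TestNullLMM:
    def test_identity_grm_matches_ols(self, rng):
        n = 120
        covs = rng.normal(size=(n, 2))
        y = covs @ [0.5, -0.2] + rng.normal(size=n)
        fit = fit_null_lmm(y, covs, np.eye(n))
        X = np.column_stack([np.ones(n), covs])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        resid = y - X @ beta_ols
        assert fit.var_g + fit.var_e == pytest.approx(
            resid @ resid / (n - 3), rel=1e-4)

    def test_variance_component_recovery(self, rng):
        K = _structured_grm(rng)
        n = K.shape[0]
        covs = rng.normal(size=(n, 2))
        vg, ve = [], []
        for _ in range(10):
            y = _draw_trait(rng, K, covs, var_g=2.0, var_e=1.0, beta_cov=np.r_[0.3, 0.1])
            fit = fit_null_lmm(y, covs, K)
            vg.append(fit.var_g)
            ve.append(fit.var_e)
        assert np.mean(vg) == pytest.approx(2.0, rel=0.25)
        assert np.mean(ve) == pytest.approx(1.0, rel=0.25)

    def test_pure_noise_gives_zero_genetic_variance(self, rng):
        K = _structured_grm(rng, n_families=30, family_size=6)
        n = K.shape[0]
        covs = rng.normal(size=(n, 1))
        vgs = [fit_null_lmm(rng.normal(size=n), covs, K).var_g for _ in range(9)]
        assert np.median(vgs) < 0.05

    def test_asymmetric_grm_rejected(self, rng):
        K = np.eye(10)
        K[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            fit_null_lmm(rng.normal(size=10), rng.normal(size=(10, 1)), K)


class TestRegionalTest:
    def test_identity_grm_p_equals_ols(self, rng):
        n = 150
        covs = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        s = (rng.random(n) < 0.2).astype(float)
        fit = fit_null_lmm(y, covs, np.eye(n))
        res = regional_wald(s, fit)
        # OLS by hand
        X = np.column_stack([np.ones(n), covs, s])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        sigma2 = r @ r / (n - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        from scipy import stats as sps
        p_ols = 2 * sps.t.sf(abs(b[-1] / se), n - 4)
        assert res.p == pytest.approx(p_ols, abs=1e-6)
        assert res.beta == pytest.approx(b[-1], abs=1e-8)

    def test_two_stage_close_to_exact_refit(self, rng):
        K = _structured_grm(rng, n_families=20, family_size=8)
        n = K.shape[0]
        covs = rng.normal(size=(n, 2))
        y = _draw_trait(rng, K, covs, 1.0, 1.0, np.r_[0.2, -0.1])
        fit = fit_null_lmm(y, covs, K)
        for _ in range(8):
            s = (rng.random(n) < 0.3).astype(float)
            p_fast = regional_wald(s, fit).p
            p_exact = reml_refit_pvalue(y, covs, s, K)
            assert p_fast == pytest.approx(p_exact, rel=0.10)

    def test_affine_trait_rescaling_leaves_p_unchanged(self, rng):
        K = _structured_grm(rng, n_families=15, family_size=6)
        n = K.shape[0]
        covs = rng.normal(size=(n, 2))
        y = _draw_trait(rng, K, covs, 0.5, 1.0, np.r_[0.2, 0.0])
        s = (rng.random(n) < 0.25).astype(float)
        r1 = regional_wald(s, fit_null_lmm(y, covs, K))
        r2 = regional_wald(s, fit_null_lmm(3.0 * y + 7.0, covs, K))
        assert r2.p == pytest.approx(r1.p, rel=1e-5)
        assert r2.beta == pytest.approx(3.0 * r1.beta, rel=1e-5)

    def test_constant_status_flagged(self, rng):
        n = 60
        fit = fit_null_lmm(rng.normal(size=n), rng.normal(size=(n, 1)), np.eye(n))
        res = regional_wald(np.ones(n), fit)
        assert res.flag == "constant_regressor"
        assert np.isnan(res.p)


def test_bonferroni_threshold_arithmetic():
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 5) == 0.01
    assert bonferroni_threshold(0.05, 410_000) == pytest.approx(1.2195e-7, rel=1e-4)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


class TestClump:
    def _gm_with_ld(self, rng, n=400):
        g1 = rng.binomial(2, 0.4, n).astype(np.int8)
        g2 = g1.copy()
        flip = rng.random(n) < 0.05
        g2[flip] = rng.binomial(2, 0.4, flip.sum())
        g3 = rng.binomial(2, 0.4, n).astype(np.int8)
        return make_matrix(np.column_stack([g1, g2, g3]),
                           pos=[100_000, 150_000, 200_000])

    def _results(self, ps):
        return [AssocResult(f"v{j}", "1", 100_000 + 50_000 * j, "regional_lmm",
                            1.0, 1.0, p) for j, p in enumerate(ps)]

    def test_hand_traced_assignment(self, rng):
        gm = self._gm_with_ld(rng)
        results = self._results([1e-10, 1e-8, 1e-9])
        clumps = clump(results, gm)
        assert clumps == {"v0": ["v1"], "v2": []}
        assert results[1].clump == "v0"

    def test_single_significant_snp(self, rng):
        gm = self._gm_with_ld(rng)
        results = self._results([1e-6, 0.5, 0.9])
        assert clump(results, gm) == {"v0": []}

    def test_above_p1_unclumped(self, rng):
        gm = self._gm_with_ld(rng)
        results = self._results([1e-3, 0.5, 0.9])
        assert clump(results, gm) == {}
        assert results[0].clump is None

    def test_row_order_invariance(self, rng):
        gm = self._gm_with_ld(rng)
        a = self._results([1e-10, 1e-8, 1e-9])
        b = self._results([1e-10, 1e-8, 1e-9])[::-1]
        assert clump(a, gm) == clump(b, gm)

    def test_kb_window_respected(self, rng):
        gm = self._gm_with_ld(rng)
        gm.variants.loc[1, "pos"] = 100_000 + 300_000  # outside 250 kb
        results = self._results([1e-10, 1e-8, 1e-9])
        results[1].pos = 400_000
        clumps = clump(results, gm)
        assert clumps["v0"] == []


class TestGenotypeModels:
    def test_encoding(self):
        calls = np.array([0, 1, 2, MISSING], dtype=np.int8)
        add = encode_genotype(calls, "additive")
        rec = encode_genotype(calls, "recessive")
        assert list(add[:3]) == [0, 1, 2] and np.isnan(add[3])
        assert list(rec[:3]) == [0, 0, 1] and np.isnan(rec[3])
        with pytest.raises(ValueError):
            encode_genotype(calls, "dominant")

    def test_beta_recovery_under_correct_model(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, n)
        covs = rng.normal(size=(n, 2))
        y = 0.8 * (g == 2) + covs @ [0.2, 0.1] + rng.normal(size=n)
        res = genotype_wald(encode_genotype(g.astype(np.int8), "recessive"),
                            y, covs, model="recessive")
        assert abs(res.beta - 0.8) < 2 * res.se

    def test_recessive_beats_additive_on_recessive_truth(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, n)
        covs = rng.normal(size=(n, 2))
        y = 1.0 * (g == 2) + rng.normal(size=n)
        p_rec = genotype_wald(encode_genotype(g.astype(np.int8), "recessive"),
                              y, covs, model="recessive").p
        p_add = genotype_wald(encode_genotype(g.astype(np.int8), "additive"),
                              y, covs, model="additive").p
        assert p_rec < p_add

    def test_null_p_uniform(self, rng):
        from scipy import stats as sps
        n = 200
        ps = []
        for _ in range(200):
            g = rng.binomial(2, 0.3, n).astype(np.int8)
            y = rng.normal(size=n)
            covs = rng.normal(size=(n, 1))
            ps.append(genotype_wald(encode_genotype(g, "additive"), y, covs).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_regressor_flagged(self, rng):
        res = genotype_wald(np.zeros(50), rng.normal(size=50),
                            rng.normal(size=(50, 1)))
        assert res.flag == "constant_regressor"

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            genotype_wald(np.r_[0.0, 1, 2, 1], rng.normal(size=4),
                          rng.normal(size=(4, 1)))


def test_regional_scan_outperforms_additive_gwas_on_regional_architecture(rng):
    """When the causal signal is autozygosity status (not allele dosage), the
    regional LMM at the causal column is far more significant than the
    additive genotype test at the causal variant."""
    from rohscan import popstruct
    from rohscan.synthetic_data import (
        SimConfig, _regional_status, choose_causal_region,
        effect_size_for_variance, simulate_genotypes, simulate_trait)

    p_regional, p_additive = [], []
    for s in range(5):
        cfg = SimConfig(n_samples=250, n_chrom=3, snps_per_chrom=700,
                        segment_rate=1.5, trait_model="regional", seed=600 + s)
        gm, truth = simulate_genotypes(cfg)
        K = popstruct.grm(gm)
        c, p0, vid = choose_causal_region(truth, gm.variants)
        status = _regional_status(truth, c, p0)
        cfg.beta_effect = effect_size_for_variance(
            status, 0.10, cfg.var_polygenic + cfg.var_noise)
        pheno = simulate_trait(cfg, gm, truth, grm=K)
        covs = np.column_stack([popstruct.pca(gm, 2).components,
                                pheno["sex"].to_numpy(float),
                                pheno["age"].to_numpy(float)])
        y = pheno["trait"].to_numpy(float)
        fit = fit_null_lmm(y, covs, K)
        p_regional.append(regional_wald(status, fit).p)
        col = int(np.flatnonzero(gm.variants["id"] == vid)[0])
        enc = encode_genotype(gm.calls[:, col], "additive")
        p_additive.append(genotype_wald(enc, y, covs, "additive").p)
    assert np.median(p_regional) < np.median(p_additive)
    assert np.median(p_regional) < 1e-4
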