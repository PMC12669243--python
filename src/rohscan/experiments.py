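"""Reproducible validation experiments at study scale.

Each function builds its own synthetic inputs with the package's generator,
runs the relevant pipeline stage, and returns the measured quantity.  They
back both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes: the recovery cohort is N=200 samples × ~20k SNPs on a 300 Mb
simulated genome; the mixed-model calibration uses 20 independent cohorts of
N=300 (≥10,000 null tests in total) and the power study 20 cohorts of N=500;
the genotype-model contrast uses 50 cohorts of N=500.  Planted-segment rates
are scaled to the simulated genome length so the planted autozygous fraction
stays at the cohort-level ≈4.7% the generator defaults encode.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import popstruct, qc, reference, regional_assoc, roh, trait_assoc
from .genotype_io import GenotypeMatrix, ROHSegment
from .roh import ROHParams
from .synthetic_data import (
    SimConfig,
    TruthRecord,
    _regional_status,
    causal_interval,
    causal_span,
    choose_causal_region,
    effect_size_for_variance,
    simulate_genotypes,
    simulate_trait,
)

#: planted autozygous genome fraction implied by the generator defaults
DEFAULT_PLANTED_FRACTION = (SimConfig.segment_rate * SimConfig.segment_mean_bp
                            / (SimConfig.n_chrom * SimConfig.snps_per_chrom
                               * SimConfig.mean_spacing_bp))


def _scaled_config(**kwargs) -> SimConfig:
    """SimConfig with segment_rate rescaled to keep the default planted fraction."""
    cfg = SimConfig(**kwargs)
    genome = cfg.n_chrom * cfg.snps_per_chrom * cfg.mean_spacing_bp
    cfg.segment_rate = DEFAULT_PLANTED_FRACTION * genome / cfg.segment_mean_bp
    return cfg


# ---------------------------------------------------------------------------
# carrier-percentage arithmetic (cohort classification and region tables)
# ---------------------------------------------------------------------------

def cohort_classification_percentages(n_samples: int = 455, n_none: int = 18,
                                      n_short_only: int = 6) -> dict[str, float]:
    """Build a cohort with the given composition and summarise it.

    ``n_none`` samples carry no segments, ``n_short_only`` carry only a
    segment at/below the long cutoff, the rest carry a long segment; the
    percentages come out of :func:`rohscan.roh.summarize`.
    """
    params = ROHParams()
    samples = [f"S{i}" for i in range(n_samples)]
    segs: list[ROHSegment] = []
    short_bp = int(params.long_cutoff_kb * 1000)          # exactly at cutoff: short
    long_bp = int(params.long_cutoff_kb * 1000 * 2)
    for i, s in enumerate(samples):
        if i < n_none:
            continue
        length = short_bp if i < n_none + n_short_only else long_bp
        segs.append(ROHSegment(sample_id=s, chrom="1", pos_start=10**6,
                               pos_end=10**6 + length - 1, n_snps=params.min_snp))
    summary = roh.summarize(segs, samples, params)
    return {
        "pct_no_roh": summary.pct_no_roh,
        "pct_short_only": summary.pct_short_only,
        "pct_any_long": summary.pct_any_long,
    }


def region_carrier_percentage(n_carriers: int = 96, n_samples: int = 455,
                              n_snps: int = 39) -> float:
    """Carrier percentage of an enriched region via the region-frequency op."""
    variant_map = pd.DataFrame({
        "chrom": "17", "id": [f"v{j}" for j in range(n_snps)],
        "pos": np.arange(1, n_snps + 1) * 1000,
    })
    inclusion = np.zeros((n_samples, n_snps), dtype=np.int8)
    inclusion[:n_carriers, :] = 1
    if n_carriers / n_samples < 0.20:   # below the enrichment threshold:
        return roh.carrier_percentage(n_carriers, n_samples)
    _, regions = roh.region_frequency(inclusion, variant_map, thresholds=(0.20,))
    assert len(regions) == 1
    return float(regions["carrier_pct"].iloc[0])


# ---------------------------------------------------------------------------
# ROH caller vs brute-force oracle
# ---------------------------------------------------------------------------

def _random_instance(rng: np.random.Generator):
    """One random chromosome: genotype mosaic, positions and caller params."""
    n = int(rng.integers(30, 501))
    pos = np.cumsum(rng.integers(1_000, 25_000, size=n)).astype(np.int64)
    calls = rng.choice([0, 1, 2], size=n, p=[0.3, 0.35, 0.35]).astype(np.int8)
    # plant a few homozygous tracts so segments actually occur
    for _ in range(int(rng.integers(0, 4))):
        s = int(rng.integers(0, n))
        ln = int(rng.integers(20, 250))
        tract = rng.choice([0, 2], size=min(ln, n - s))
        calls[s:s + tract.size] = tract
    # sprinkle noise
    for code, rate in ((1, 0.01), (-1, 0.02)):
        mask = rng.random(n) < rate
        calls[mask] = code
    params = ROHParams(
        window_snp=int(rng.integers(5, 61)),
        window_het_max=int(rng.integers(0, 3)),
        window_missing_max=int(rng.integers(0, 7)),
        window_threshold=float(rng.choice([0.01, 0.05, 0.2])),
        min_snp=int(rng.integers(10, 121)),
        min_kb=float(rng.integers(100, 1500)),
        max_density_kb_per_snp=float(rng.integers(10, 61)),
        max_gap_kb=float(rng.integers(100, 1001)),
    )
    return calls, pos, params


def roh_oracle_agreement(n_instances: int = 200, seed: int = 0) -> float:
    """Fraction of random instances where the optimised caller and the
    brute-force oracle agree exactly (eligibility flags and segments)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        calls, pos, params = _random_instance(rng)
        fast = roh.window_scan(calls, params)
        slow = reference.brute_window_scan(calls, params)
        if not np.array_equal(fast, slow):
            continue
        variants = pd.DataFrame({
            "chrom": "1", "id": [f"v{j}" for j in range(calls.size)],
            "cm": 0.0, "pos": pos, "allele1": "A", "allele2": "G",
        })
        gm = GenotypeMatrix(samples=["s1"], variants=variants, calls=calls[None, :])
        fast_segs = [(s.pos_start, s.pos_end, s.n_snps)
                     for s in roh.call_segments(gm, params)]
        slow_segs = reference.brute_call_segments(calls, pos, params)
        if fast_segs == slow_segs:
            agree += 1
    return agree / n_instances


# ---------------------------------------------------------------------------
# HWE exact test vs exact-rational enumeration
# ---------------------------------------------------------------------------

def hwe_oracle_sweep(max_n: int = 25) -> tuple[float, int]:
    """Max |p_fast − p_exact| over every genotype-count triple with N ≤ max_n."""
    worst, count = 0.0, 0
    for n in range(1, max_n + 1):
        for n1 in range(n + 1):
            for nh in range(n - n1 + 1):
                n2 = n - n1 - nh
                fast = qc.hwe_exact(n1, nh, n2)
                exact = float(reference.hwe_exact_fraction(n1, nh, n2))
                worst = max(worst, abs(fast - exact))
                count += 1
    return worst, count


# ---------------------------------------------------------------------------
# planted-segment recovery
# ---------------------------------------------------------------------------

def _interval_jaccard(truth_ivs, called_ivs) -> tuple[float, float]:
    """(intersection bp, union bp) of two interval sets keyed by (sample, chrom)."""
    from collections import defaultdict

    def total_len(by_key):
        t = 0
        for ivs in by_key.values():
            ivs.sort()
            last = -1
            for s, e in ivs:
                s = max(s, last + 1)
                if e >= s:
                    t += e - s + 1
                    last = max(last, e)
        return t

    a = defaultdict(list)
    b = defaultdict(list)
    for key, s, e in truth_ivs:
        a[key].append((s, e))
    for key, s, e in called_ivs:
        b[key].append((s, e))
    inter = 0
    for key in set(a) & set(b):
        for s1, e1 in a[key]:
            for s2, e2 in b[key]:
                lo, hi = max(s1, s2), min(e1, e2)
                if hi >= lo:
                    inter += hi - lo + 1
    union = total_len(a) + total_len(b) - inter
    return inter, union


def segment_recovery(seed: int = 0, n_samples: int = 200) -> dict[str, float]:
    """Error-free cohort: bp-Jaccard of called vs planted segments and the
    correlation of estimated F_ROH with the true autozygous fraction."""
    cfg = _scaled_config(n_samples=n_samples, genotype_error_rate=0.0, seed=seed)
    gm, truth = simulate_genotypes(cfg)
    params = ROHParams(genome_length_bp=truth.genome_length_bp)
    segments = roh.call_segments(gm, params)

    truth_ivs = [((i, c), s, e) for i, segs in enumerate(truth.segments)
                 for c, s, e in segs]
    called_ivs = [((gm.samples.index(sg.sample_id), sg.chrom), sg.pos_start, sg.pos_end)
                  for sg in segments]
    inter, union = _interval_jaccard(truth_ivs, called_ivs)
    jaccard = inter / union if union else 1.0

    fr = roh.froh(segments, gm.samples, params).to_numpy()
    r = float(np.corrcoef(fr, truth.true_fraction)[0, 1])
    return {"jaccard": jaccard, "froh_truth_r": r, "n_samples": n_samples,
            "n_variants": gm.n_variants}


# ---------------------------------------------------------------------------
# mixed-model calibration and power
# ---------------------------------------------------------------------------

def _cohort_for_lmm(cfg: SimConfig, rng_seed: int):
    """Simulate a cohort and everything the regional scan needs."""
    cfg = replace(cfg, seed=rng_seed)
    gm, truth = simulate_genotypes(cfg)
    K = popstruct.grm(gm)
    pcs = popstruct.pca(gm, 2)
    segments = roh.call_segments(
        gm, ROHParams(genome_length_bp=truth.genome_length_bp))
    inclusion = roh.inclusion_matrix(segments, gm.variants, gm.samples)
    return cfg, gm, truth, K, pcs, inclusion


def lmm_type1_error(seed: int = 0, n_cohorts: int = 20, n_samples: int = 300,
                    snps_per_cohort: int = 500) -> dict[str, float]:
    """Empirical size of the regional LMM test at α = 0.05 on null traits.

    Each cohort contributes ``snps_per_cohort`` evenly spaced regional-status
    columns; the trait has covariate, polygenic and noise components but no
    regional effect.  Returns the pooled rejection rate, the total test
    count, and the between-cohort standard error of the rate (status columns
    within a cohort are correlated, so the honest SE is clustered).
    """
    base = _scaled_config(n_samples=n_samples, n_chrom=4, snps_per_chrom=1500,
                          trait_model="null")
    rates = []
    n_tests = 0
    for c in range(n_cohorts):
        cfg, gm, truth, K, pcs, inclusion = _cohort_for_lmm(base, seed * 100_003 + c)
        pheno = simulate_trait(cfg, gm, truth, grm=K)
        filt, kept_samples, _, _ = regional_assoc.filter_for_association(
            inclusion, gm.samples)
        idx = [gm.samples.index(s) for s in kept_samples]
        covs = np.column_stack([pcs.components[idx, :2],
                                pheno["sex"].to_numpy(float)[idx],
                                pheno["age"].to_numpy(float)[idx]])
        y = pheno["trait"].to_numpy(float)[idx]
        fit = regional_assoc.fit_null_lmm(y, covs, K[np.ix_(idx, idx)])
        cols = np.linspace(0, filt.shape[1] - 1, min(snps_per_cohort, filt.shape[1]),
                           dtype=int)
        cols = np.unique(cols)
        res = regional_assoc.scan_regional(filt[:, cols], fit)
        p = np.array([r.p for r in res])
        p = p[~np.isnan(p)]
        rates.append(float((p < 0.05).mean()))
        n_tests += p.size
    rates = np.asarray(rates)
    return {
        "type1_error": float(rates.mean()),
        "n_tests": n_tests,
        "se_clustered": float(rates.std(ddof=1) / np.sqrt(len(rates))),
    }


def lmm_power(seed: int = 0, n_seeds: int = 20, n_samples: int = 500,
              variance_fraction: float = 0.08,
              p_threshold: float = 1e-8) -> dict[str, float]:
    """Power of the regional scan at a planted causal region.

    The effect explains ``variance_fraction`` of the non-covariate trait
    variance; success is a minimum p below ``p_threshold`` among status
    columns inside the planted locus (the union span of carrier segments
    through the causal position — the region a scan reader would call the
    signal).  Cohorts use the generator's default map (10 chromosomes ×
    2000 SNPs).
    """
    base = SimConfig(n_samples=n_samples, trait_model="regional")
    hits = 0
    for s in range(n_seeds):
        cfg, gm, truth, K, pcs, inclusion = _cohort_for_lmm(base, seed * 999_983 + s)
        c, p0, _ = choose_causal_region(truth, gm.variants)
        status = _regional_status(truth, c, p0)
        cfg.beta_effect = effect_size_for_variance(
            status, variance_fraction, cfg.var_polygenic + cfg.var_noise)
        pheno = simulate_trait(cfg, gm, truth, grm=K)
        filt, kept_samples, kept_cols, _ = regional_assoc.filter_for_association(
            inclusion, gm.samples)
        idx = [gm.samples.index(ss) for ss in kept_samples]
        covs = np.column_stack([pcs.components[idx, :2],
                                pheno["sex"].to_numpy(float)[idx],
                                pheno["age"].to_numpy(float)[idx]])
        y = pheno["trait"].to_numpy(float)[idx]
        fit = regional_assoc.fit_null_lmm(y, covs, K[np.ix_(idx, idx)])
        lo, hi = causal_span(truth, c, p0)
        vmap = gm.variants.iloc[kept_cols]
        near = np.flatnonzero((vmap["chrom"].to_numpy() == c)
                              & (vmap["pos"].to_numpy() >= lo)
                              & (vmap["pos"].to_numpy() <= hi))
        if near.size == 0:
            continue
        res = regional_assoc.scan_regional(filt[:, near], fit)
        pmin = np.nanmin([r.p for r in res])
        hits += pmin < p_threshold
    return {"power": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# recessive vs additive genotype models
# ---------------------------------------------------------------------------

def recessive_contrast(seed: int = 0, n_seeds: int = 50, n_samples: int = 500,
                       beta_sd: float = 0.5) -> dict[str, float]:
    """Fraction of cohorts where the recessive test beats the additive test
    at a purely recessive causal variant (effect ``beta_sd`` residual SDs)."""
    wins = 0
    for s in range(n_seeds):
        cfg = SimConfig(n_samples=n_samples, n_chrom=2, snps_per_chrom=400,
                        segment_rate=0.0, var_polygenic=0.0,
                        trait_model="recessive", beta_effect=beta_sd,
                        seed=seed * 7_368_787 + s)
        gm, truth = simulate_genotypes(cfg)
        pcs = popstruct.pca(gm, 2)
        pheno = simulate_trait(cfg, gm, truth)
        covs = np.column_stack([pcs.components[:, :2],
                                pheno["sex"].to_numpy(float),
                                pheno["age"].to_numpy(float)])
        y = pheno["trait"].to_numpy(float)
        col = int(np.flatnonzero(gm.variants["id"] == truth.causal_variant_id)[0])
        calls = gm.calls[:, col]
        p_by_model = {}
        for model in ("additive", "recessive"):
            enc = regional_assoc.encode_genotype(calls, model)
            p_by_model[model] = regional_assoc.test_genotype(enc, y, covs, model).p
        wins += p_by_model["recessive"] < p_by_model["additive"]
    return {"recessive_wins": wins / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# small hand-checked operations
# ---------------------------------------------------------------------------

def small_op_examples() -> dict[str, float]:
    """Recompute the hand-checkable small operations.

    Returns the Spearman rho of the 5-point rank example, the first BH
    step-up value of the 4-p-value example, the Bonferroni threshold for
    410k tests at α = 0.05, and whether greedy clumping reproduces its
    hand-traced assignment (1.0 = match).
    """
    rho, _ = trait_assoc.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    adj = trait_assoc.bh_adjust([0.005, 0.01, 0.03, 0.04])
    bonf = regional_assoc.bonferroni_threshold(0.05, 410_000)

    # 3 SNPs: p = 1e-10, 1e-8, 1e-9; SNP2 in LD with SNP1, SNP3 independent
    rng = np.random.default_rng(42)
    n = 400
    g1 = rng.binomial(2, 0.4, n).astype(np.int8)
    g2 = g1.copy()
    flip = rng.random(n) < 0.05                 # r²(1,2) ≈ 0.9
    g2[flip] = rng.binomial(2, 0.4, flip.sum())
    g3 = rng.binomial(2, 0.4, n).astype(np.int8)
    variants = pd.DataFrame({
        "chrom": "1", "id": ["snpA", "snpB", "snpC"], "cm": 0.0,
        "pos": [100_000, 150_000, 200_000], "allele1": "A", "allele2": "G",
    })
    gm = GenotypeMatrix(samples=[f"s{i}" for i in range(n)], variants=variants,
                        calls=np.column_stack([g1, g2, g3]))
    results = [
        regional_assoc.AssocResult("snpA", "1", 100_000, "regional_lmm", 1, 1, 1e-10),
        regional_assoc.AssocResult("snpB", "1", 150_000, "regional_lmm", 1, 1, 1e-8),
        regional_assoc.AssocResult("snpC", "1", 200_000, "regional_lmm", 1, 1, 1e-9),
    ]
    clumps = regional_assoc.clump(results, gm)
    match = float(clumps == {"snpA": ["snpB"], "snpC": []})
    return {"spearman_rho": rho, "bh_first_adjusted": float(adj[0]),
            "bonferroni_410k": bonf, "clump_match": match}
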