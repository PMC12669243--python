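"""Variant and sample quality control.

Filters, applied in order: variant missingness, sample missingness,
Hardy–Weinberg exact-test departure, per-sample heterozygosity outliers
(mean ± 3 SD), minor allele frequency.  The report records counts removed at
each step so the order is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class QCThresholds:
    geno_max_missing: float = 0.02
    mind_max_missing: float = 0.10
    hwe_min_p: float = 5e-8
    het_sd: float = 3.0
    maf_min: float = 0.05

    def validate(self) -> None:
        for name in ("geno_max_missing", "mind_max_missing", "maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 < self.hwe_min_p < 1:
            raise ValueError("hwe_min_p outside (0, 1)")
        if self.het_sd <= 0:
            raise ValueError("het_sd must be > 0")


@dataclass
class QCReport:
    """Counts removed at each step, in application order."""

    variants_missingness: int = 0
    samples_missingness: int = 0
    variants_hwe: int = 0
    samples_heterozygosity: int = 0
    variants_maf: int = 0
    n_samples_in: int = 0
    n_variants_in: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


class AllSamplesRemovedError(RuntimeError):
    def __init__(self, report: QCReport):
        super().__init__("quality control removed every sample")
        self.report = report


def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy–Weinberg exact test (conditional on allele counts).

    With the minor-allele count fixed, the heterozygote count follows the
    Levene–Haldane distribution P(h) ∝ N!/(n1!·h!·n2!)·2^h; the p-value sums
    the probabilities of all heterozygote counts no more probable than the
    observed one.  Computed with the standard ratio recurrence in doubles;
    symmetric in (n_hom1, n_hom2).  Monomorphic variants return 1.0.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    minor = 2 * min(n_hom1, n_hom2) + n_het
    if minor == 0 or minor == 2 * n:
        return 1.0

    # possible het counts share the parity of the minor-allele count
    h_max = min(minor, 2 * n - minor)
    h_min = h_max % 2
    hs = list(range(h_min, h_max + 1, 2))
    probs = {h_min: 1.0}
    h = h_min
    while h + 2 <= h_max:
        # P(h+2)/P(h) = 4·n1(h)·n2(h) / ((h+2)(h+1))  with n1+n2 shrinking by 1 each
        n1 = (minor - h) // 2
        n2 = n - h - n1
        probs[h + 2] = probs[h] * 4.0 * n1 * n2 / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    obs = probs[n_het]
    # tolerance guards float noise when summing "<= observed probability"
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-10)) / total
    return min(1.0, p)


def hwe_exact_vector(calls: np.ndarray) -> np.ndarray:
    """Per-variant HWE p-values for an N×M call matrix (missing ignored)."""
    m = calls.shape[1]
    out = np.ones(m)
    for j in range(m):
        col = calls[:, j]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        if n0 + n1 + n2:
            out[j] = hwe_exact(n2, n1, n0)
    return out


def heterozygosity_rate(calls: np.ndarray, variant_mask: np.ndarray | None = None) -> np.ndarray:
    """Observed het calls / non-missing calls per sample over masked variants."""
    if variant_mask is not None:
        calls = calls[:, variant_mask]
    het = (calls == 1).sum(axis=1)
    nonmiss = (calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, het / nonmiss, np.nan)


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the filter cascade; returns the filtered matrix and the report.

    Heterozygosity is computed on MAF-eligible variants (MAF ≥ ``maf_min`` on
    the current sample set) before those failing MAF are removed, and its
    mean/SD are computed once (not iterated).
    """
    th = thresholds or QCThresholds()
    th.validate()
    report = QCReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants)

    # 1. variant missingness
    miss_v = (gm.calls == MISSING).mean(axis=0)
    keep_v = miss_v <= th.geno_max_missing
    report.variants_missingness = int((~keep_v).sum())
    gm = gm.subset(variant_idx=np.flatnonzero(keep_v))

    # 2. sample missingness
    if gm.n_variants:
        miss_s = (gm.calls == MISSING).mean(axis=1)
    else:
        miss_s = np.zeros(gm.n_samples)
    keep_s = miss_s <= th.mind_max_missing
    report.samples_missingness = int((~keep_s).sum())
    gm = gm.subset(sample_idx=np.flatnonzero(keep_s))
    if gm.n_samples == 0:
        report.n_samples_out = 0
        raise AllSamplesRemovedError(report)

    # 3. HWE exact test (keep if p > threshold)
    p_hwe = hwe_exact_vector(gm.calls)
    keep_v = p_hwe > th.hwe_min_p
    report.variants_hwe = int((~keep_v).sum())
    gm = gm.subset(variant_idx=np.flatnonzero(keep_v))

    # 4. heterozygosity outliers, on MAF-eligible variants
    eligible = gm.maf() >= th.maf_min
    het = heterozygosity_rate(gm.calls, eligible if eligible.any() else None)
    mu, sd = np.nanmean(het), np.nanstd(het)
    if sd > 0:
        keep_s = np.abs(het - mu) <= th.het_sd * sd
    else:
        keep_s = np.ones(gm.n_samples, dtype=bool)
    keep_s &= ~np.isnan(het)
    report.samples_heterozygosity = int((~keep_s).sum())
    gm = gm.subset(sample_idx=np.flatnonzero(keep_s))
    if gm.n_samples == 0:
        report.n_samples_out = 0
        raise AllSamplesRemovedError(report)

    # 5. MAF (recomputed on remaining samples)
    keep_v = gm.maf() >= th.maf_min
    report.variants_maf = int((~keep_v).sum())
    gm = gm.subset(variant_idx=np.flatnonzero(keep_v))

    report.n_samples_out = gm.n_samples
    report.n_variants_out = gm.n_variants
    return gm, report
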