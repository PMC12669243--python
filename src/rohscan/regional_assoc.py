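"""Per-SNP regional-autozygosity association under a linear mixed model.

Model: trait = Xβ + s·b + g + e with fixed covariates X (intercept, PC1,
PC2, sex, age), the per-SNP regional-autozygosity status s, a polygenic
random effect g ~ N(0, σ²_g·K) structured by the genomic relationship
matrix K, and residual e ~ N(0, σ²_e·I).

The variance components are estimated once under the null (no SNP) by REML:
K is eigendecomposed a single time and the restricted likelihood profiled
over the heritability ratio h = σ²_g/(σ²_g+σ²_e) by 1-D bounded
optimisation.  Per-SNP tests are then two-stage generalised least squares
Wald tests with the variance ratio held fixed (the overall scale is
re-estimated per SNP, so with K = I the test reduces exactly to OLS).

Also provides Bonferroni thresholding, greedy LD clumping, and the
additive/recessive genotype-model validation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class NullModelFit:
    """REML fit of the covariates-only mixed model."""

    beta: np.ndarray              # fixed effects (intercept first)
    var_g: float
    var_e: float
    loglik: float                 # restricted log-likelihood at the optimum
    eigvals: np.ndarray           # GRM eigenvalues
    rotation: np.ndarray          # GRM eigenvectors U (y* = Uᵀy)
    x_rot: np.ndarray             # UᵀX
    y_rot: np.ndarray             # Uᵀy
    covariate_names: list[str] = field(default_factory=list)

    @property
    def heritability(self) -> float:
        tot = self.var_g + self.var_e
        return self.var_g / tot if tot > 0 else 0.0

    def weights(self) -> np.ndarray:
        """Per-eigencomponent marginal variances σ²_g λ_i + σ²_e."""
        return self.var_g * self.eigvals + self.var_e


@dataclass
class AssocResult:
    variant_id: str
    chrom: str
    pos: int
    model: str                    # regional_lmm | additive | recessive
    beta: float
    se: float
    p: float
    frequency: float = float("nan")
    n_used: int = 0
    clump: Optional[str] = None
    flag: str = ""                # e.g. "constant_regressor"


@dataclass
class FilterReport:
    n_samples_in: int = 0
    n_samples_removed: int = 0
    n_snps_in: int = 0
    n_snps_removed: int = 0


def filter_for_association(inclusion: np.ndarray, samples: Sequence[str],
                           freq_min: float = 0.01
                           ) -> tuple[np.ndarray, list[str], np.ndarray, FilterReport]:
    """Drop zero-ROH samples, then SNP columns below the frequency floor.

    Frequencies are computed on the remaining samples.  Returns the filtered
    matrix, remaining sample ids, kept column indices and a count report.
    """
    inclusion = np.asarray(inclusion)
    report = FilterReport(n_samples_in=inclusion.shape[0], n_snps_in=inclusion.shape[1])
    has_roh = inclusion.sum(axis=1) > 0
    report.n_samples_removed = int((~has_roh).sum())
    sub = inclusion[has_roh]
    kept_samples = [s for s, k in zip(samples, has_roh) if k]
    freq = sub.mean(axis=0) if sub.shape[0] else np.zeros(inclusion.shape[1])
    keep_col = freq >= freq_min
    report.n_snps_removed = int((~keep_col).sum())
    if not keep_col.any():
        raise ValueError("no SNP columns survive the regional-frequency filter")
    return sub[:, keep_col], kept_samples, np.flatnonzero(keep_col), report


def _reml_neg_loglik(h: float, lam: np.ndarray, x_rot: np.ndarray,
                     y_rot: np.ndarray) -> float:
    n, p = x_rot.shape
    w = h * lam + (1.0 - h)
    xw = x_rot / w[:, None]
    xtx = x_rot.T @ xw
    xty = xw.T @ y_rot
    beta = np.linalg.solve(xtx, xty)
    r = y_rot - x_rot @ beta
    rss = float(r @ (r / w))
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + np.sum(np.log(w))
                 + logdet_xtx + (n - p))
    return -ll


def fit_null_lmm(trait: np.ndarray, covariates: np.ndarray, grm: np.ndarray,
                 covariate_names: Optional[list[str]] = None) -> NullModelFit:
    """REML variance components and GLS fixed effects for the null model.

    ``covariates`` is N×p *without* an intercept column (one is prepended).
    Inputs must be complete cases; the GRM must be symmetric PSD.
    """
    y = np.asarray(trait, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("complete cases required (NaN present)")
    K = np.asarray(grm, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("GRM is not symmetric")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ValueError("GRM is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)

    y_rot = U.T @ y
    x_rot = U.T @ X
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        args=(lam, x_rot, y_rot), options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML optimiser failed: {res.message}")
    h = float(res.x)
    # degenerate edge: compare with the OLS boundary explicitly
    if _reml_neg_loglik(0.0, lam, x_rot, y_rot) < res.fun:
        h, res_fun = 0.0, _reml_neg_loglik(0.0, lam, x_rot, y_rot)
    else:
        res_fun = res.fun

    n, p = x_rot.shape
    w = h * lam + (1.0 - h)
    xw = x_rot / w[:, None]
    beta = np.linalg.solve(x_rot.T @ xw, xw.T @ y_rot)
    r = y_rot - x_rot @ beta
    sigma2 = float(r @ (r / w)) / (n - p)
    names = covariate_names or [f"x{i}" for i in range(X.shape[1] - 1)]
    return NullModelFit(
        beta=beta, var_g=h * sigma2, var_e=(1.0 - h) * sigma2,
        loglik=-res_fun, eigvals=lam, rotation=U, x_rot=x_rot, y_rot=y_rot,
        covariate_names=["intercept"] + list(names),
    )


def _gls_scan(S_rot: np.ndarray, fit: NullModelFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald tests of each rotated regressor column added to the null design.

    Whitens by the null-fit weights, residualises against the whitened
    covariates (Frisch–Waugh), and re-estimates the residual scale per SNP;
    returns (beta, se, p) arrays with NaN for constant regressors.
    """
    w = fit.weights()
    sw = np.sqrt(w)
    Xw = fit.x_rot / sw[:, None]
    yw = fit.y_rot / sw
    Sw = S_rot / sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    y_r = yw - Q @ (Q.T @ yw)
    S_r = Sw - Q @ (Q.T @ Sw)

    ss = np.einsum("ij,ij->j", S_r, S_r)
    sy = S_r.T @ y_r
    n, p = Xw.shape
    df = n - p - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sy / ss
        rss = float(y_r @ y_r) - beta**2 * ss
        sigma2 = rss / df
        se = np.sqrt(sigma2 / ss)
        t = beta / se
        pval = 2.0 * stats.t.sf(np.abs(t), df)
    bad = ss <= 1e-12 * n
    beta[bad] = np.nan
    se[bad] = np.nan
    pval[bad] = np.nan
    return beta, se, pval


def scan_regional(status: np.ndarray, fit: NullModelFit,
                  variant_info: Optional[pd.DataFrame] = None) -> list[AssocResult]:
    """Two-stage LMM Wald test of every regional-status column.

    ``status`` is N×m binary in the same sample order as the null fit.
    Constant columns are flagged (``constant_regressor``), not tested.
    """
    S = np.asarray(status, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    S_rot = fit.rotation.T @ S
    beta, se, pval = _gls_scan(S_rot, fit)
    freq = S.mean(axis=0)
    out = []
    for j in range(S.shape[1]):
        if variant_info is not None:
            vid = str(variant_info["id"].iloc[j])
            chrom = str(variant_info["chrom"].iloc[j])
            pos = int(variant_info["pos"].iloc[j])
        else:
            vid, chrom, pos = f"col{j}", "", 0
        flag = "constant_regressor" if np.isnan(beta[j]) else ""
        out.append(AssocResult(
            variant_id=vid, chrom=chrom, pos=pos, model="regional_lmm",
            beta=float(beta[j]), se=float(se[j]), p=float(pval[j]),
            frequency=float(freq[j]), n_used=S.shape[0], flag=flag,
        ))
    return out


def test_regional(status_column: np.ndarray, fit: NullModelFit,
                  variant_info: Optional[pd.DataFrame] = None) -> AssocResult:
    """Single-SNP convenience wrapper around :func:`scan_regional`."""
    return scan_regional(np.asarray(status_column), fit, variant_info)[0]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold α / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def encode_genotype(calls: np.ndarray, model: str) -> np.ndarray:
    """Genotype regressor: additive dosage 0/1/2 or recessive 1[dosage == 2].

    Missing calls stay missing (NaN in the returned float array).
    """
    calls = np.asarray(calls)
    out = calls.astype(float)
    out[calls == MISSING] = np.nan
    if model == "additive":
        return out
    if model == "recessive":
        with np.errstate(invalid="ignore"):
            rec = (out == 2.0).astype(float)
        rec[np.isnan(out)] = np.nan
        return rec
    raise ValueError(f"unknown genotype model {model!r}")


def test_genotype(regressor: np.ndarray, trait: np.ndarray, covariates: np.ndarray,
                  model: str = "additive",
                  variant_id: str = "", chrom: str = "", pos: int = 0) -> AssocResult:
    """OLS Wald test of an encoded genotype regressor with fixed covariates.

    Complete-case analysis; requires ≥ 10 complete cases and a non-constant
    regressor (otherwise flagged, not tested).
    """
    x = np.asarray(regressor, dtype=float)
    y = np.asarray(trait, dtype=float)
    C = np.asarray(covariates, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[ok], y[ok], C[ok]
    if x.size < 10:
        raise ValueError(f"need >= 10 complete cases, got {x.size}")
    base = AssocResult(variant_id=variant_id, chrom=chrom, pos=pos, model=model,
                       beta=float("nan"), se=float("nan"), p=float("nan"),
                       n_used=int(x.size))
    if np.ptp(x) == 0:
        base.flag = "constant_regressor"
        return base
    X = np.column_stack([np.ones(x.size), C, x])
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta_hat
    df = x.size - X.shape[1]
    sigma2 = float(r @ r) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[-1, -1]))
    t = beta_hat[-1] / se
    base.beta, base.se = float(beta_hat[-1]), se
    base.p = float(2.0 * stats.t.sf(abs(t), df))
    base.frequency = float(np.nanmean(x) / (2.0 if model == "additive" else 1.0))
    return base


def clump(results: Sequence[AssocResult], gm: GenotypeMatrix,
          p1: float = 1e-4, p2: float = 0.01, r2_min: float = 0.5,
          kb: float = 250.0) -> dict[str, list[str]]:
    """Greedy LD clumping of association results around index SNPs.

    Repeatedly takes the most significant unassigned SNP with p ≤ ``p1`` as
    an index and assigns to it every unassigned SNP within ``kb`` kilobases
    with p ≤ ``p2`` and dosage r² > ``r2_min`` against the index.  Ties in p
    break on variant id, so assignments are independent of input order.
    Returns {index variant id: [member ids]} and writes ``clump`` tags onto
    the results.
    """
    id_to_col = {str(v): j for j, v in enumerate(gm.variants["id"])}
    usable = [r for r in results if r.p == r.p and r.variant_id in id_to_col]
    order = sorted(usable, key=lambda r: (r.p, r.variant_id))
    assigned: set[str] = set()
    clumps: dict[str, list[str]] = {}

    X = gm.calls.astype(float)
    X[gm.calls == MISSING] = np.nan

    def r2(a: str, b: str) -> float:
        xa, xb = X[:, id_to_col[a]], X[:, id_to_col[b]]
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
            return 0.0
        return float(np.corrcoef(xa[ok], xb[ok])[0, 1] ** 2)

    for idx in order:
        if idx.variant_id in assigned or idx.p > p1:
            continue
        members = []
        for cand in order:
            if cand.variant_id in assigned or cand.variant_id == idx.variant_id:
                continue
            if cand.chrom != idx.chrom or abs(cand.pos - idx.pos) > kb * 1000.0:
                continue
            if cand.p <= p2 and r2(idx.variant_id, cand.variant_id) > r2_min:
                members.append(cand.variant_id)
                assigned.add(cand.variant_id)
                cand.clump = idx.variant_id
        assigned.add(idx.variant_id)
        idx.clump = idx.variant_id
        clumps[idx.variant_id] = members
    return clumps


def results_to_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "pos": r.pos, "id": r.variant_id, "model": r.model,
        "freq": r.frequency, "beta": r.beta, "se": r.se, "p": r.p,
        "clump": r.clump, "flag": r.flag, "n_used": r.n_used,
    } for r in results])
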