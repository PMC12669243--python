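"""Population-structure machinery: cohort merging on shared common variants,
LD pruning, principal components and the genomic relationship matrix.

The GRM is the VanRaden form Z Zᵀ / Σ 2p_j(1−p_j) with Z the column-centred
dosage matrix; PCA standardises dosages by √(2p(1−p)) and eigendecomposes
the sample covariance — the same spectral object, so GRM eigenvectors and
genotype PCs agree up to sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCResult:
    components: np.ndarray        # N×k unit-norm sample scores
    variance_fraction: np.ndarray # per-component eigenvalue / trace


def _imputed_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Float dosages with missing calls mean-imputed; returns (X, allele1 freq)."""
    X = gm.calls.astype(float)
    X[gm.calls == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    col_mean = 2.0 * p
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return X, p


def intersect_common(a: GenotypeMatrix, b: GenotypeMatrix,
                     labels: tuple[str, str] = ("A", "B"),
                     maf_min: float = 0.05) -> GenotypeMatrix:
    """Merge two cohorts on shared common variants (MAF > ``maf_min`` in each).

    Variants are matched by (chrom, pos) with identical allele pairs; a
    swapped allele1/allele2 order in ``b`` is accepted with genotype codes
    flipped (0 ↔ 2).  Samples are concatenated with their cohort label
    prefixed to keep ids unique.
    """
    maf_a, maf_b = a.maf(), b.maf()
    key_b = {}
    for j, v in enumerate(b.variants.itertuples(index=False)):
        key_b[(str(v.chrom), int(v.pos))] = j

    keep_a, keep_b, flip = [], [], []
    for i, v in enumerate(a.variants.itertuples(index=False)):
        j = key_b.get((str(v.chrom), int(v.pos)))
        if j is None:
            continue
        w = b.variants.iloc[j]
        if (v.allele1, v.allele2) == (w["allele1"], w["allele2"]):
            swapped = False
        elif (v.allele1, v.allele2) == (w["allele2"], w["allele1"]):
            swapped = True
        else:
            continue
        if maf_a[i] > maf_min and maf_b[j] > maf_min:
            keep_a.append(i)
            keep_b.append(j)
            flip.append(swapped)
    if not keep_a:
        raise ValueError("no shared common variants between cohorts")

    calls_a = a.calls[:, keep_a]
    calls_b = b.calls[:, keep_b].copy()
    flip = np.asarray(flip)
    if flip.any():
        cols = calls_b[:, flip]
        swapped_cols = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        calls_b[:, flip] = swapped_cols
    merged = GenotypeMatrix(
        samples=[f"{labels[0]}:{s}" for s in a.samples]
        + [f"{labels[1]}:{s}" for s in b.samples],
        variants=a.variants.iloc[keep_a].reset_index(drop=True),
        calls=np.vstack([calls_a, calls_b]),
    )
    return merged


def _pairwise_r2(X: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    if not miss.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
        return np.nan_to_num(r) ** 2
    # pairwise-complete moments via 0-filled data and presence indicators
    W = (~miss).astype(float)
    X0 = np.where(miss, 0.0, X)
    n = W.T @ W                      # complete pairs per column pair
    Sa = X0.T @ W                    # Σ x_a over pairs complete with b
    Saa = (X0 * X0).T @ W
    Sab = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sab - Sa * Sa.T
        var_a = n * Saa - Sa**2
        r2 = cov**2 / (var_a * var_a.T)
    r2[(n < 2) | ~np.isfinite(r2)] = 0.0
    return r2


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept variant indices (map order).

    Within each 50-SNP window (advanced by 5 SNPs, in SNP counts), while any
    pair of kept variants has r² > ``r2_max``, one member of the worst
    (highest-r²) pair is removed: the one with the lower MAF, or the later
    one in map order on ties.  Output is independent of sample order.
    """
    maf = gm.maf()
    keep = np.ones(gm.n_variants, dtype=bool)
    miss_all = gm.calls == MISSING
    X_all = gm.calls.astype(float)

    for chrom, grp in gm.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        for start in range(0, len(cols), step_snps):
            win = cols[start:start + window_snps]
            live = win[keep[win]]
            if live.size < 2:
                continue
            r2 = _pairwise_r2(X_all[:, live], miss_all[:, live])
            np.fill_diagonal(r2, 0.0)
            alive = np.ones(live.size, dtype=bool)
            while True:
                sub = r2[np.ix_(alive, alive)]
                if sub.size == 0 or sub.max() <= r2_max:
                    break
                ai = np.flatnonzero(alive)
                i, j = np.unravel_index(np.argmax(sub), sub.shape)
                vi, vj = live[ai[i]], live[ai[j]]
                if maf[vi] < maf[vj] or (maf[vi] == maf[vj] and vi > vj):
                    drop = ai[i]
                else:
                    drop = ai[j]
                alive[drop] = False
            removed = live[~alive]
            keep[removed] = False
    return np.flatnonzero(keep)


def pca(gm: GenotypeMatrix, k: int) -> PCResult:
    """Top-k principal components of standardised genotypes.

    Dosages are mean-imputed, centred at 2p and scaled by √(2p(1−p));
    components are unit-norm eigenvectors of the sample covariance,
    variance fractions are eigenvalues over the trace.
    """
    if k > min(gm.n_samples, gm.n_variants):
        raise ValueError(f"k={k} exceeds min(N, M)")
    X, p = _imputed_dosage(gm)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    Z = (X[:, ok] - 2.0 * p[ok]) / denom[ok]
    C = Z @ Z.T / Z.shape[1]
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    trace = float(np.trace(C))
    return PCResult(
        components=U[:, order],
        variance_fraction=np.clip(w[order] / trace, 0.0, 1.0),
    )


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix; monomorphic variants excluded."""
    X, p = _imputed_dosage(gm)
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluded %d monomorphic variant(s) from GRM", n_mono)
    Z = X[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0
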