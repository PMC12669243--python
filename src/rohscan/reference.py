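"""Naive reference implementations for validation.

Each function here restates a pipeline rule in the most literal way
possible — explicit loops, exact rational arithmetic, full model refits —
trading speed for transparency.  They exist to cross-check the optimised
implementations on small instances and are not meant for production-size
data.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np
from scipy import optimize, stats

from .genotype_io import MISSING
from .roh import ROHParams


def brute_window_scan(calls: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Literal window enumeration: per-SNP eligibility for one sample."""
    p = params or ROHParams()
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = min(p.window_snp, n)
    windows = []
    for s in range(0, n - w + 1):
        seg = calls[s:s + w]
        ok = ((seg == 1).sum() <= p.window_het_max
              and (seg == MISSING).sum() <= p.window_missing_max)
        windows.append((s, s + w - 1, ok))
    eligible = np.zeros(n, dtype=bool)
    for i in range(n):
        containing = [ok for (s, e, ok) in windows if s <= i <= e]
        frac = sum(containing) / len(containing)
        eligible[i] = frac >= p.window_threshold
    return eligible


def brute_call_segments(calls: np.ndarray, pos: np.ndarray,
                        params: ROHParams | None = None) -> list[tuple[int, int, int]]:
    """Literal segment emission for one sample on one chromosome.

    Returns (pos_start, pos_end, n_snps) triples.
    """
    p = params or ROHParams()
    eligible = brute_window_scan(calls, p)
    segs = []
    run: list[int] = []

    def flush(run):
        if not run:
            return
        n_snps = len(run)
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        kb = (end - start + 1) / 1000.0
        if (n_snps >= p.min_snp and kb >= p.min_kb
                and kb / n_snps <= p.max_density_kb_per_snp):
            segs.append((start, end, n_snps))

    for i in range(len(calls)):
        if not eligible[i]:
            flush(run)
            run = []
            continue
        if run and (pos[i] - pos[run[-1]]) > p.max_gap_kb * 1000.0:
            flush(run)
            run = []
        run.append(i)
    flush(run)
    return segs


def hwe_exact_fraction(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact-rational Hardy–Weinberg test p-value (Levene–Haldane).

    Enumerates every admissible heterozygote count with integer multinomial
    weights N!/(n1!·h!·n2!)·2^h; the weights sum to C(2N, minor allele
    count), so the p-value is an exact Fraction.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    minor = 2 * min(n_hom1, n_hom2) + n_het
    if minor == 0 or minor == 2 * n:
        return Fraction(1)

    def weight(h: int) -> int:
        n1 = (minor - h) // 2
        n2 = n - h - n1
        return factorial(n) // (factorial(n1) * factorial(h) * factorial(n2)) * 2**h

    h_max = min(minor, 2 * n - minor)
    hs = range(h_max % 2, h_max + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    assert total == comb(2 * n, minor)
    obs = weights[n_het]
    return Fraction(sum(v for v in weights.values() if v <= obs), total)


def reml_refit_pvalue(y: np.ndarray, X_base: np.ndarray, s: np.ndarray,
                      K: np.ndarray) -> float:
    """Exact per-SNP mixed-model p-value with the SNP in the REML design.

    Refits the variance components from scratch with the tested column
    included among the fixed effects, then returns the GLS Wald p for that
    column — the slow exact counterpart of the two-stage scan.
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X_base, float), np.asarray(s, float)])
    lam, U = np.linalg.eigh(np.asarray(K, float))
    lam = np.clip(lam, 0.0, None)
    y_rot, x_rot = U.T @ y, U.T @ X
    n, p = x_rot.shape

    def neg_ll(h):
        w = h * lam + (1 - h)
        xw = x_rot / w[:, None]
        xtx = x_rot.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ y_rot)
        r = y_rot - x_rot @ beta
        sigma2 = float(r @ (r / w)) / (n - p)
        _, logdet = np.linalg.slogdet(xtx)
        return 0.5 * ((n - p) * np.log(2 * np.pi * sigma2)
                      + np.sum(np.log(w)) + logdet + (n - p))

    res = optimize.minimize_scalar(neg_ll, bounds=(0.0, 1 - 1e-9), method="bounded",
                                   options={"xatol": 1e-10})
    h = float(res.x)
    if neg_ll(0.0) < res.fun:
        h = 0.0
    w = h * lam + (1 - h)
    xw = x_rot / w[:, None]
    xtx_inv = np.linalg.inv(x_rot.T @ xw)
    beta = xtx_inv @ (xw.T @ y_rot)
    r = y_rot - x_rot @ beta
    sigma2 = float(r @ (r / w)) / (n - p)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta[-1] / se
    return float(2.0 * stats.t.sf(abs(t), n - p))


def spearman_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value for Spearman rho (all n! orderings).

    Feasible only for tiny n; two-sided on |rho|.
    """
    from itertools import permutations

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def rho(a, b):
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        return np.corrcoef(ra, rb)[0, 1]

    obs = abs(rho(x, y))
    count = 0
    total = 0
    for perm in permutations(range(len(y))):
        total += 1
        if abs(rho(x, y[list(perm)])) >= obs - 1e-12:
            count += 1
    return count / total
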