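"""Genome-wide autozygosity–trait association.

Spearman rank correlation of per-sample F_ROH against each quantitative
trait (the non-parametric choice, since traits such as urinary ACR are
heavily skewed), with Benjamini–Hochberg adjustment across the trait family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationResult:
    trait: str
    rho: float
    p: float
    p_adjusted: float
    n_used: int

    @property
    def defined(self) -> bool:
        return self.rho == self.rho  # not NaN


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (ties averaged) with the two-sided t-approximation p.

    Pairs with a missing value in either vector are dropped.  A constant
    vector leaves rho undefined: (nan, nan) is returned, not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need at least 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    # a perfect rank correlation yields p = 0 from the t-approximation;
    # clamp to keep p in (0, 1] for downstream adjustment
    return float(rho), float(max(p, np.finfo(float).tiny))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def froh_trait_scan(frame: pd.DataFrame, traits: list[str],
                    froh_col: str = "froh") -> list[CorrelationResult]:
    """Correlate F_ROH with each trait; BH-adjust across the trait family.

    Missing trait values are dropped pairwise.  Traits whose correlation is
    undefined (constant values) are flagged with NaN and excluded from the
    BH family.
    """
    if froh_col not in frame:
        raise KeyError(f"column {froh_col!r} absent from frame")
    missing = [t for t in traits if t not in frame]
    if missing:
        raise KeyError(f"trait(s) absent from frame: {', '.join(missing)}")
    if not traits:
        raise ValueError("no traits requested")

    results = []
    for t in traits:
        x = frame[froh_col].to_numpy(dtype=float)
        y = frame[t].to_numpy(dtype=float)
        n_used = int((~(np.isnan(x) | np.isnan(y))).sum())
        rho, p = spearman(x, y)
        results.append(CorrelationResult(t, rho, p, float("nan"), n_used))

    defined = [r for r in results if r.defined]
    if defined:
        adj = bh_adjust([r.p for r in defined])
        for r, a in zip(defined, adj):
            r.p_adjusted = float(a)
    return results


def scan_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"trait": r.trait, "rho": r.rho, "p": r.p,
          "p_adjusted": r.p_adjusted, "n_used": r.n_used} for r in results]
    )
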