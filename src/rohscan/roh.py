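"""Runs-of-homozygosity calling, the per-SNP inclusion matrix and summaries.

The caller follows the classic sliding-window scheme: windows of
``window_snp`` consecutive SNPs pass when they contain at most
``window_het_max`` heterozygous and ``window_missing_max`` missing calls; a
SNP is eligible when at least ``window_threshold`` of the windows containing
it pass; maximal runs of consecutive eligible SNPs — split at inter-SNP gaps
above ``max_gap_kb`` — are emitted as segments when they meet the minimum
SNP count, minimum length and maximum kb/SNP density.  Defaults are the
reference tool's ``--homozyg`` family defaults.  Only the per-window
heterozygote cap applies; a final segment has no separate heterozygote cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ROHSegment

logger = logging.getLogger(__name__)


@dataclass
class ROHParams:
    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    long_cutoff_kb: float = 1600.0
    genome_length_bp: float = 3e9

    def validate(self) -> None:
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold outside (0, 1]")
        for name in ("window_snp", "min_snp", "min_kb", "max_density_kb_per_snp",
                     "max_gap_kb", "long_cutoff_kb", "genome_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSummary:
    """Per-sample and cohort homozygosity measures."""

    per_sample: pd.DataFrame        # sample_id, n_segments, total_length_bp, froh
    avg_n_roh: float
    avg_total_length_bp: float
    n_no_roh: int
    n_short_only: int               # only segments <= long cutoff
    n_any_long: int                 # at least one segment > long cutoff
    pct_no_roh: float
    pct_short_only: float
    pct_any_long: float


def window_scan(calls: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP eligibility flags for one chromosome.

    ``calls`` is 1-D (one sample) or 2-D (samples × SNPs); the result has the
    same shape, boolean.  Windows live in SNP index space and lie fully
    inside the chromosome; a chromosome shorter than the window is scanned
    with a single truncated window.
    """
    p = params or ROHParams()
    p.validate()
    squeeze = calls.ndim == 1
    c = np.atleast_2d(calls)
    n_snp = c.shape[1]
    if n_snp == 0:
        out = np.zeros_like(c, dtype=bool)
        return out[0] if squeeze else out

    het = (c == 1).astype(np.int32)
    mis = (c == MISSING).astype(np.int32)
    w = min(p.window_snp, n_snp)
    if w < p.window_snp:
        logger.info("chromosome has %d < %d SNPs; single truncated window", n_snp, p.window_snp)

    # sliding sums over windows of length w
    cum_h = np.concatenate([np.zeros((c.shape[0], 1), np.int32), np.cumsum(het, axis=1)], axis=1)
    cum_m = np.concatenate([np.zeros((c.shape[0], 1), np.int32), np.cumsum(mis, axis=1)], axis=1)
    n_win = n_snp - w + 1
    h_cnt = cum_h[:, w:] - cum_h[:, :-w]
    m_cnt = cum_m[:, w:] - cum_m[:, :-w]
    passes = (h_cnt <= p.window_het_max) & (m_cnt <= p.window_missing_max)

    # SNP i is contained in windows j in [i-w+1, i] ∩ [0, n_win)
    cum_p = np.concatenate([np.zeros((c.shape[0], 1), np.int32),
                            np.cumsum(passes.astype(np.int32), axis=1)], axis=1)
    idx = np.arange(n_snp)
    lo = np.clip(idx - w + 1, 0, n_win - 1)
    hi = np.minimum(idx, n_win - 1)
    n_pass = cum_p[:, hi + 1] - cum_p[:, lo]
    n_total = hi - lo + 1
    frac = n_pass / n_total
    eligible = frac >= p.window_threshold
    return eligible[0] if squeeze else eligible


def _segments_for_sample_chrom(eligible: np.ndarray, pos: np.ndarray, calls: np.ndarray,
                               ids: np.ndarray, sample_id: str, chrom: str,
                               p: ROHParams) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return out
    # break runs at index discontinuities or bp gaps above the cap
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > p.max_gap_kb * 1000.0)
    )
    for run in np.split(idx, breaks + 1):
        n_snps = run.size
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        kb = (end - start + 1) / 1000.0
        if n_snps < p.min_snp or kb < p.min_kb or kb / n_snps > p.max_density_kb_per_snp:
            continue
        seg_calls = calls[run]
        nonmiss = int((seg_calls != MISSING).sum())
        n_het = int((seg_calls == 1).sum())
        out.append(ROHSegment(
            sample_id=sample_id, chrom=chrom, pos_start=start, pos_end=end,
            n_snps=n_snps, snp1=str(ids[run[0]]), snp2=str(ids[run[-1]]),
            phom=(nonmiss - n_het) / n_snps, phet=n_het / n_snps,
        ))
    return out


def call_segments(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample of the cohort."""
    p = params or ROHParams()
    p.validate()
    segments: list[ROHSegment] = []
    for chrom, grp in gm.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        ids = grp["id"].to_numpy()
        calls = gm.calls[:, cols]
        eligible = window_scan(calls, p)
        for i, sid in enumerate(gm.samples):
            segments.extend(
                _segments_for_sample_chrom(eligible[i], pos, calls[i], ids, sid, str(chrom), p)
            )
    return segments


def inclusion_matrix(segments: Sequence[ROHSegment], variant_map: pd.DataFrame,
                     samples: Sequence[str]) -> np.ndarray:
    """N×M binary matrix: 1 iff the variant lies inside a sample's segment.

    Boundary SNPs (position equal to a segment endpoint) count as inside.
    """
    sample_idx = {s: i for i, s in enumerate(samples)}
    chrom = variant_map["chrom"].to_numpy()
    pos = variant_map["pos"].to_numpy()
    out = np.zeros((len(samples), len(variant_map)), dtype=np.int8)
    chrom_cols = {c: np.flatnonzero(chrom == c) for c in np.unique(chrom)}
    for seg in segments:
        if seg.sample_id not in sample_idx:
            raise KeyError(f"segment references unknown sample {seg.sample_id!r}")
        cols = chrom_cols.get(str(seg.chrom))
        if cols is None:
            continue
        pc = pos[cols]
        inside = cols[(pc >= seg.pos_start) & (pc <= seg.pos_end)]
        out[sample_idx[seg.sample_id], inside] = 1
    return out


def froh(segments: Sequence[ROHSegment], samples: Sequence[str],
         params: ROHParams | None = None) -> pd.Series:
    """Per-sample F_ROH = total segment length (bp) / autosomal genome length."""
    p = params or ROHParams()
    total = pd.Series(0.0, index=list(samples))
    for seg in segments:
        total[seg.sample_id] += seg.length_bp
    out = total / p.genome_length_bp
    out.name = "froh"
    return out


def summarize(segments: Sequence[ROHSegment], samples: Sequence[str],
              params: ROHParams | None = None) -> ROHSummary:
    """Cohort homozygosity summary; percentages are reported to one decimal."""
    p = params or ROHParams()
    n = len(samples)
    if n == 0:
        raise ValueError("no samples to summarize")
    per = pd.DataFrame({"sample_id": list(samples)}).set_index("sample_id")
    per["n_segments"] = 0
    per["total_length_bp"] = 0.0
    per["max_length_kb"] = 0.0
    for seg in segments:
        per.loc[seg.sample_id, "n_segments"] += 1
        per.loc[seg.sample_id, "total_length_bp"] += seg.length_bp
        per.loc[seg.sample_id, "max_length_kb"] = max(
            per.loc[seg.sample_id, "max_length_kb"], seg.length_kb)
    per["froh"] = per["total_length_bp"] / p.genome_length_bp

    none = per["n_segments"] == 0
    any_long = per["max_length_kb"] > p.long_cutoff_kb
    short_only = ~none & ~any_long
    pct = lambda k: round(100.0 * k / n, 1)
    return ROHSummary(
        per_sample=per.reset_index(),
        avg_n_roh=len(segments) / n,
        avg_total_length_bp=float(per["total_length_bp"].sum()) / n,
        n_no_roh=int(none.sum()), n_short_only=int(short_only.sum()),
        n_any_long=int(any_long.sum()),
        pct_no_roh=pct(int(none.sum())), pct_short_only=pct(int(short_only.sum())),
        pct_any_long=pct(int(any_long.sum())),
    )


def carrier_percentage(n_carriers: int, n_samples: int) -> float:
    """Carriers as a percentage of the cohort, to one decimal."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round(100.0 * n_carriers / n_samples, 1)


def region_frequency(inclusion: np.ndarray, variant_map: pd.DataFrame,
                     thresholds: Sequence[float] = (0.20, 0.15)
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP ROH frequency plus enriched-region tables.

    Returns ``(per_snp, regions)``.  ``per_snp`` has chrom, pos, id and the
    column-mean frequency.  For each threshold, contiguous runs of SNPs with
    frequency ≥ threshold are merged into regions; a sample is a carrier of
    a region when its ROH covers at least one SNP of the region.
    """
    freq = inclusion.mean(axis=0)
    per_snp = variant_map[["chrom", "id", "pos"]].copy()
    per_snp["frequency"] = freq

    n = inclusion.shape[0]
    rows = []
    chrom_arr = variant_map["chrom"].to_numpy()
    pos_arr = variant_map["pos"].to_numpy()
    for thr in thresholds:
        for chrom in pd.unique(chrom_arr):
            cols = np.flatnonzero(chrom_arr == chrom)
            hot = freq[cols] >= thr
            idx = np.flatnonzero(hot)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                rcols = cols[run]
                carriers = int((inclusion[:, rcols].max(axis=1) > 0).sum())
                rows.append({
                    "threshold": thr, "chrom": str(chrom),
                    "start": int(pos_arr[rcols[0]]), "end": int(pos_arr[rcols[-1]]),
                    "n_snps": int(run.size), "n_carriers": carriers,
                    "carrier_pct": carrier_percentage(carriers, n),
                })
    regions = pd.DataFrame(
        rows, columns=["threshold", "chrom", "start", "end", "n_snps",
                       "n_carriers", "carrier_pct"])
    return per_snp, regions
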