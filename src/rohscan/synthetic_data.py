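"""Synthetic cohorts with planted autozygous segments and trait effects.

The generator emulates the statistical structure of an isolated-population
WGS cohort: common biallelic SNPs (MAF ≥ 5%), individuals carrying a handful
of long (multi-megabase) autozygous segments, genotyping error expressed as
spurious heterozygosity, missing calls, a polygenic trait component
structured by the genomic relationship matrix, and an optional causal effect
that is linear in F_ROH, linear in regional autozygosity status, or
recessive in genotype.

Autozygosity is planted directly — inside a planted segment one haplotype is
drawn per site and duplicated — rather than via pedigree or coalescent
simulation.  Defaults are sized so the expected planted genome fraction is
≈4.7%, in line with the mean autozygous fraction of strongly isolated human
populations, with segment lengths of 2–10 Mb so planted runs comfortably
exceed a default ROH caller's minimums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

TRAIT_MODELS = ("null", "froh_linear", "regional", "recessive")


@dataclass
class SimConfig:
    """Cohort-generator settings.

    Rates are probabilities in [0, 1]; lengths are base pairs.  Planted
    segment lengths follow a shifted exponential: ``min_bp`` plus an
    exponential with mean ``mean_bp − min_bp``.
    """

    n_samples: int = 200
    n_chrom: int = 10
    snps_per_chrom: int = 2000
    mean_spacing_bp: float = 15_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    segment_rate: float = 4.0            # expected planted segments per genome
    segment_min_bp: float = 2_000_000.0
    segment_mean_bp: float = 3_500_000.0
    genotype_error_rate: float = 0.001   # call corrupted to het
    missing_rate: float = 0.005
    trait_model: str = "null"
    beta_effect: float = 0.0
    var_polygenic: float = 0.2
    var_noise: float = 1.0
    beta_age: float = 0.01
    beta_sex: float = 0.2
    causal_maf_target: float = 0.40      # recessive model: pick variant nearest this MAF
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if lo < 0.05:
            raise ValueError("maf_range low bound must be >= 0.05 (common variants only)")
        if self.segment_min_bp <= 0:
            raise ValueError("segment_min_bp must be > 0")
        if self.segment_mean_bp < self.segment_min_bp:
            raise ValueError("segment_mean_bp must be >= segment_min_bp")
        if self.trait_model not in TRAIT_MODELS:
            raise ValueError(f"unknown trait_model {self.trait_model!r}")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery checks.

    ``segments[i]`` holds sample i's planted autozygous intervals as
    ``(chrom, start_bp, end_bp)`` (1-based inclusive, non-overlapping);
    ``true_fraction[i]`` is the planted share of the simulated genome.
    Causal fields are populated when a trait effect is planted.
    """

    segments: list[list[tuple[str, int, int]]]
    true_fraction: np.ndarray
    genome_length_bp: float
    chrom_lengths: dict[str, int]
    allele1_freq: np.ndarray
    clean_calls: Optional[np.ndarray] = None   # pre-error, pre-missing genotypes
    causal_chrom: Optional[str] = None
    causal_start: Optional[int] = None
    causal_end: Optional[int] = None
    causal_variant_id: Optional[str] = None
    causal_status: Optional[np.ndarray] = None
    true_beta: float = 0.0

    def to_json(self, path) -> None:
        obj = {
            "segments": self.segments,
            "true_fraction": self.true_fraction.tolist(),
            "genome_length_bp": self.genome_length_bp,
            "chrom_lengths": self.chrom_lengths,
            "causal_chrom": self.causal_chrom,
            "causal_start": self.causal_start,
            "causal_end": self.causal_end,
            "causal_variant_id": self.causal_variant_id,
            "true_beta": self.true_beta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def simulate_map(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Variant map: per chromosome, positions are cumulative exponential spacings."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for c in range(1, config.n_chrom + 1):
        spacing = np.maximum(
            1, rng.exponential(config.mean_spacing_bp, size=config.snps_per_chrom).round()
        ).astype(np.int64)
        pos = np.cumsum(spacing)
        for k, p in enumerate(pos):
            rows.append((str(c), f"snp{c}_{k + 1}", 0.0, int(p), "A", "G"))
    return pd.DataFrame(rows, columns=["chrom", "id", "cm", "pos", "allele1", "allele2"])


def _plant_segments(config: SimConfig, chrom_lengths: dict[str, int],
                    rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Draw one sample's planted intervals; overlaps within a chromosome merged."""
    chroms = list(chrom_lengths)
    k = rng.poisson(config.segment_rate)
    raw: dict[str, list[tuple[int, int]]] = {}
    for _ in range(k):
        chrom = chroms[rng.integers(len(chroms))]
        clen = chrom_lengths[chrom]
        length = int(config.segment_min_bp
                     + rng.exponential(config.segment_mean_bp - config.segment_min_bp))
        start = int(rng.integers(1, max(2, clen)))
        end = min(start + length - 1, clen)  # truncated at chromosome end
        raw.setdefault(chrom, []).append((start, end))
    out: list[tuple[str, int, int]] = []
    for chrom, ivs in raw.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def simulate_genotypes(config: SimConfig,
                       variant_map: Optional[pd.DataFrame] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Generate the cohort's call matrix plus its ground truth.

    Outside planted segments genotypes follow Hardy–Weinberg proportions at
    each variant's allele frequency; inside a segment a single haplotype is
    drawn per site and duplicated (calls ∈ {0, 2}).  Each call is then
    corrupted to heterozygous with probability ``genotype_error_rate`` and
    set missing with probability ``missing_rate``, independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if variant_map is None:
        variant_map = simulate_map(config, rng=rng)

    chrom_lengths = {
        str(c): int(g["pos"].max()) for c, g in variant_map.groupby("chrom", sort=False)
    }
    genome_len = float(sum(chrom_lengths.values()))
    n, m = config.n_samples, len(variant_map)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    pos = variant_map["pos"].to_numpy()
    chrom = variant_map["chrom"].to_numpy()

    calls = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)

    segments: list[list[tuple[str, int, int]]] = []
    true_fraction = np.zeros(n)
    for i in range(n):
        segs = _plant_segments(config, chrom_lengths, rng)
        segments.append(segs)
        total = 0
        for c, s, e in segs:
            total += e - s + 1
            inside = (chrom == c) & (pos >= s) & (pos <= e)
            n_in = int(inside.sum())
            if n_in:
                hap = rng.random(n_in) < freqs[inside]
                calls[i, inside] = np.where(hap, 2, 0).astype(np.int8)
        true_fraction[i] = total / genome_len

    clean = calls.copy()
    err = rng.random((n, m)) < config.genotype_error_rate
    calls[err] = 1
    miss = rng.random((n, m)) < config.missing_rate
    calls[miss] = MISSING

    samples = [f"S{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, variants=variant_map.copy(), calls=calls)
    truth = TruthRecord(
        segments=segments, true_fraction=true_fraction,
        genome_length_bp=genome_len, chrom_lengths=chrom_lengths,
        allele1_freq=freqs, clean_calls=clean,
    )
    return gm, truth


def _regional_status(truth: TruthRecord, chrom: str, pos: int) -> np.ndarray:
    """1 iff a sample's planted segments cover the given position."""
    out = np.zeros(len(truth.segments))
    for i, segs in enumerate(truth.segments):
        out[i] = float(any(c == chrom and s <= pos <= e for c, s, e in segs))
    return out


def causal_interval(truth: TruthRecord, chrom: str, pos: int) -> tuple[int, int]:
    """Intersection of the carrier segments through ``pos``: the interval on
    which every carrier is autozygous, i.e. where regional status equals the
    causal status exactly.  Falls back to (pos, pos) with no carriers."""
    lo, hi = None, None
    for segs in truth.segments:
        for c, s, e in segs:
            if c == chrom and s <= pos <= e:
                lo = s if lo is None else max(lo, s)
                hi = e if hi is None else min(hi, e)
    if lo is None:
        return pos, pos
    return lo, hi


def causal_span(truth: TruthRecord, chrom: str, pos: int) -> tuple[int, int]:
    """Union span of the carrier segments through ``pos``: the full extent of
    the planted locus, the region over which a genome scan would read the
    signal.  Falls back to (pos, pos) with no carriers."""
    lo, hi = None, None
    for segs in truth.segments:
        for c, s, e in segs:
            if c == chrom and s <= pos <= e:
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
    if lo is None:
        return pos, pos
    return lo, hi


def choose_causal_region(truth: TruthRecord, variant_map: pd.DataFrame
                         ) -> tuple[str, int, str]:
    """Pick the variant position covered by the most planted segments.

    Planting the effect where autozygosity actually occurs keeps the causal
    regressor non-degenerate at modest sample sizes.  Returns
    (chrom, pos, variant_id); ties break to the first variant in map order.
    """
    chrom = variant_map["chrom"].to_numpy()
    pos = variant_map["pos"].to_numpy()
    counts = np.zeros(len(variant_map))
    for segs in truth.segments:
        for c, s, e in segs:
            counts += (chrom == c) & (pos >= s) & (pos <= e)
    j = int(np.argmax(counts))
    return str(chrom[j]), int(pos[j]), str(variant_map["id"].iloc[j])


def effect_size_for_variance(status: np.ndarray, variance_fraction: float,
                             background_var: float) -> float:
    """β such that β²·Var(status) explains ``variance_fraction`` of the trait
    variance not due to covariates: β²Var(s) = f/(1−f)·background_var."""
    v = float(np.var(status))
    if v == 0:
        raise ValueError("causal status is constant; cannot place an effect")
    return float(np.sqrt(variance_fraction / (1.0 - variance_fraction) * background_var / v))


def simulate_trait(config: SimConfig, gm: GenotypeMatrix, truth: TruthRecord,
                   grm: Optional[np.ndarray] = None,
                   rng: Optional[np.random.Generator] = None,
                   trait_name: str = "trait") -> pd.DataFrame:
    """Simulate covariates and a quantitative trait; updates ``truth`` in place
    with the causal region/variant when an effect is planted.

    trait = β_age·age + β_sex·sex + causal term + polygenic (GRM-structured)
    + N(0, var_noise).  Ages are uniform on 18–80; sex is Bernoulli(0.5)
    coded 0/1 (female/male).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003) if rng is None else rng
    n = gm.n_samples
    age = rng.uniform(18, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)

    causal = np.zeros(n)
    if config.trait_model == "froh_linear":
        causal = config.beta_effect * truth.true_fraction
        truth.true_beta = config.beta_effect
    elif config.trait_model == "regional":
        c, p, vid = choose_causal_region(truth, gm.variants)
        status = _regional_status(truth, c, p)
        causal = config.beta_effect * status
        truth.causal_chrom = c
        truth.causal_start, truth.causal_end = causal_interval(truth, c, p)
        truth.causal_variant_id, truth.causal_status = vid, status
        truth.true_beta = config.beta_effect
    elif config.trait_model == "recessive":
        maf = gm.maf() if truth.clean_calls is None else np.minimum(
            truth.allele1_freq, 1 - truth.allele1_freq)
        j = int(np.argmin(np.abs(maf - config.causal_maf_target)))
        g = (truth.clean_calls[:, j] if truth.clean_calls is not None
             else gm.calls[:, j])
        status = (g == 2).astype(float)
        causal = config.beta_effect * status
        v = gm.variants.iloc[j]
        truth.causal_chrom, truth.causal_start = str(v["chrom"]), int(v["pos"])
        truth.causal_end, truth.causal_variant_id = int(v["pos"]), str(v["id"])
        truth.causal_status, truth.true_beta = status, config.beta_effect

    poly = np.zeros(n)
    if config.var_polygenic > 0:
        if grm is None:
            raise ValueError("grm required when var_polygenic > 0")
        w, U = np.linalg.eigh(np.asarray(grm))
        w = np.clip(w, 0.0, None)
        poly = U @ (np.sqrt(config.var_polygenic * w) * rng.standard_normal(n))

    noise = rng.normal(0.0, np.sqrt(config.var_noise), size=n)
    trait = config.beta_age * age + config.beta_sex * sex + causal + poly + noise
    return pd.DataFrame({
        "sample_id": gm.samples, "sex": sex.astype(int), "age": age, trait_name: trait,
    })
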