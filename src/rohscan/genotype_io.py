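"""Genotype, variant-map, segment and phenotype file I/O.

Formats handled
---------------
* PLINK binary trios (``.bed``/``.bim``/``.fam``), variant-major 2-bit coding,
  read and written bit-exactly.
* VCF 4.x (GT field only, biallelic records) via :mod:`cyvcf2`.
* ``.hom`` ROH segment tables (PLINK dialect).
* Phenotype/covariate TSV (``sample_id``, ``sex``, ``age``, trait columns).

Conventions
-----------
Genotype calls count copies of ``allele1`` (the A1 / effect allele) and are
stored as ``int8``: 0, 1, 2, with :data:`MISSING` (−1) for no-calls.
Coordinates are 1-based and inclusive on both ends; segment length in bp is
``pos_end − pos_start + 1``.  Only autosomes are processed: non-autosomal
records are dropped on read with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

#: .bed magic bytes followed by the variant-major mode byte
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (per sample, low bits first within a byte):
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies)
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

VARIANT_COLUMNS = ["chrom", "id", "cm", "pos", "allele1", "allele2"]

HOM_COLUMNS = [
    "FID", "IID", "PHE", "CHR", "SNP1", "SNP2",
    "POS1", "POS2", "KB", "NSNP", "DENSITY", "PHOM", "PHET",
]


class VariantRecord(NamedTuple):
    """A single biallelic autosomal variant (1-based position)."""

    chrom: str
    id: str
    pos: int
    allele1: str
    allele2: str


class GenotypeFormatError(ValueError):
    """Malformed genotype file (bad magic, truncated payload, missing GT)."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic calls for N samples × M variants.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers, unique.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, id, cm, pos, allele1,
        allele2``; sorted by position within each chromosome.
    calls : numpy.ndarray of int8, shape (N, M)
        Copies of ``allele1`` per call; ``-1`` marks missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant ids")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,missing}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        for _, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions not strictly increasing within a chromosome")
        same = self.variants["allele1"] == self.variants["allele2"]
        if same.any():
            raise ValueError("allele1 must differ from allele2")

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order; indices are positional."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    def allele1_freq(self) -> np.ndarray:
        """Per-variant frequency of allele1 over non-missing calls (NaN if all missing)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(str(r.chrom), str(r.id), int(r.pos), str(r.allele1), str(r.allele2))
            for r in self.variants.itertuples(index=False)
        ]


@dataclass
class ROHSegment:
    """One called (or planted) run of homozygosity, 1-based inclusive."""

    sample_id: str
    chrom: str
    pos_start: int
    pos_end: int
    n_snps: int
    snp1: str = ""
    snp2: str = ""
    phom: float = float("nan")
    phet: float = 0.0

    @property
    def length_bp(self) -> int:
        return self.pos_end - self.pos_start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def _is_autosome(chrom: str) -> bool:
    c = str(chrom).removeprefix("chr")
    return c.isdigit() and 1 <= int(c) <= 22


def _drop_non_autosomes(variants: pd.DataFrame, calls: np.ndarray):
    keep = variants["chrom"].map(_is_autosome).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d non-autosomal variant(s)", n_drop)
        return variants.loc[keep].reset_index(drop=True), calls[:, keep]
    return variants, calls


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_bed(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam trio into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to the .bed path with swapped suffix.
    The .bed must start with the variant-major magic bytes; the payload must
    hold exactly ``M * ceil(N/4)`` bytes.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    variants = pd.read_csv(
        bim_path, sep=r"\s+", header=None, names=VARIANT_COLUMNS,
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    n, m = len(samples), len(variants)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic bytes {raw[:3]!r}; expected variant-major .bed"
        )
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_variant:
        raise GenotypeFormatError(
            f"{bed_path}: payload holds {payload.size} bytes, expected "
            f"{m} variants × {bytes_per_variant} bytes"
        )
    if m:
        blocks = payload.reshape(m, bytes_per_variant)
        # expand each byte into four 2-bit codes, low bits first
        codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (blocks >> (2 * k)) & 0b11
        calls = _CODE_TO_CALL[codes[:, :n]].T
    else:
        calls = np.empty((n, 0), dtype=np.int8)

    variants, calls = _drop_non_autosomes(variants, calls)
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_bed(gm: GenotypeMatrix, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam; ``read_bed`` round-trips bit-exactly."""
    gm.validate()  # refuses unsorted/invalid matrices
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n, m = gm.n_samples, gm.n_variants
    bytes_per_variant = (n + 3) // 4
    padded = n + (-n) % 4
    codes = np.zeros((m, padded), dtype=np.uint8)
    call_codes = np.select(
        [gm.calls == 2, gm.calls == MISSING, gm.calls == 1, gm.calls == 0],
        [0b00, 0b01, 0b10, 0b11],
    ).astype(np.uint8)
    codes[:, :n] = call_codes.T
    packed = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = gm.variants[VARIANT_COLUMNS] if "cm" in gm.variants else gm.variants.assign(cm=0)[VARIANT_COLUMNS]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {"fid": gm.samples, "iid": gm.samples, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (GT only) counting the ALT allele as allele1.

    GT 1/1 → 2, 0/1 → 1, 0/0 → 0, ./. → missing.  Multiallelic records are
    skipped with a logged count; non-autosomal records are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, gts = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append((str(rec.CHROM), rec.ID or f"{rec.CHROM}:{rec.POS}", 0.0,
                     rec.POS, rec.ALT[0], rec.REF))
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing — ALT copies directly
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF record(s)", n_multi)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = np.array(gts, dtype=np.int8).T if gts else np.empty((len(samples), 0), dtype=np.int8)
    variants, calls = _drop_non_autosomes(variants, calls)
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal uncompressed VCF 4.2 (GT only; allele1 as ALT)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.allele2}\t{v.allele1}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# .hom segment tables
# ---------------------------------------------------------------------------

def write_hom(segments: Sequence[ROHSegment], path) -> None:
    """Write segments as a PLINK-style .hom table (KB = (POS2−POS1+1)/1000)."""
    rows = []
    for s in segments:
        kb = s.length_kb
        rows.append({
            "FID": s.sample_id, "IID": s.sample_id, "PHE": -9, "CHR": s.chrom,
            "SNP1": s.snp1, "SNP2": s.snp2, "POS1": s.pos_start, "POS2": s.pos_end,
            "KB": round(kb, 3), "NSNP": s.n_snps,
            "DENSITY": round(kb / s.n_snps, 4) if s.n_snps else float("nan"),
            "PHOM": round(s.phom, 4) if s.phom == s.phom else "",
            "PHET": round(s.phet, 4),
        })
    pd.DataFrame(rows, columns=HOM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hom(path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str, "CHR": str, "SNP1": str, "SNP2": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(ROHSegment(
            sample_id=str(r.IID), chrom=str(r.CHR),
            pos_start=int(r.POS1), pos_end=int(r.POS2), n_snps=int(r.NSNP),
            snp1="" if pd.isna(r.SNP1) else str(r.SNP1),
            snp2="" if pd.isna(r.SNP2) else str(r.SNP2),
            phom=float(r.PHOM) if r.PHOM == r.PHOM else float("nan"),
            phet=float(r.PHET) if r.PHET == r.PHET else 0.0,
        ))
    return out


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (sample_id, sex, age, trait columns).

    ``sex`` may be coded male/female or 1/0 and is returned as 0/1
    (female/male).  Sample ids must be unique; ages, where present, must be
    non-negative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    if "sex" in df:
        df["sex"] = (
            df["sex"].map({"male": 1, "female": 0, "M": 1, "F": 0, 1: 1, 0: 0, "1": 1, "0": 0})
        )
    if "age" in df and (df["age"].dropna() < 0).any():
        raise ValueError("negative age in phenotype table")
    return df


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
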