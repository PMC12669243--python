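import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import MISSING, GenotypeMatrix
from rohscan.synthetic_data import SimConfig, simulate_genotypes


def make_matrix(calls, chrom=None, pos=None, samples=None) -> GenotypeMatrix:
    """Small helper: wrap a raw call array in a valid GenotypeMatrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else (np.arange(m) + 1) * 1000
    variants = pd.DataFrame({
        "chrom": [str(c) for c in chrom],
        "id": [f"v{j}" for j in range(m)],
        "cm": 0.0,
        "pos": pos,
        "allele1": "A",
        "allele2": "G",
    })
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample, 3-chromosome cohort with planted segments (seeded)."""
    cfg = SimConfig(n_samples=60, n_chrom=3, snps_per_chrom=600,
                    segment_rate=1.5, seed=11)
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
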