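"""Validate a signal with additive vs recessive genotype encodings.

Simulates a purely recessive causal variant — the trait shifts only for
homozygous carriers of the effect allele — and tests it under both
encodings with covariate-adjusted least squares.  Under a recessive
architecture the recessive model should give the (much) smaller p-value:
this is the genotype-level validation step that follows a regional
autozygosity hit.
"""

import numpy as np

from rohscan import popstruct, regional_assoc
from rohscan.synthetic_data import SimConfig, simulate_genotypes, simulate_trait

cfg = SimConfig(n_samples=500, n_chrom=2, snps_per_chrom=400,
                segment_rate=0.0, var_polygenic=0.0,
                trait_model="recessive", beta_effect=0.5, seed=12)
gm, truth = simulate_genotypes(cfg)
pheno = simulate_trait(cfg, gm, truth)
covs = np.column_stack([popstruct.pca(gm, 2).components,
                        pheno["sex"].to_numpy(float),
                        pheno["age"].to_numpy(float)])
y = pheno["trait"].to_numpy(float)
col = int(np.flatnonzero(gm.variants["id"] == truth.causal_variant_id)[0])

print(f"causal variant {truth.causal_variant_id}: "
      f"{(gm.calls[:, col] == 2).sum()} homozygous carriers of {gm.n_samples}")
for model in ("additive", "recessive"):
    enc = regional_assoc.encode_genotype(gm.calls[:, col], model)
    r = regional_assoc.test_genotype(enc, y, covs, model)
    print(f"{model:9s}: beta={r.beta:+.3f}  se={r.se:.3f}  p={r.p:.2e}")
print("\nThe recessive p-value should be orders of magnitude smaller: the"
      "\nadditive dosage dilutes an effect that only homozygotes carry.")
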