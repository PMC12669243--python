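"""Correlate genome-wide autozygosity (F_ROH) with quantitative traits.

Plants a trait that increases linearly with each person's autozygous genome
fraction (the pattern reported for kidney-damage markers in isolated
cohorts), adds an unrelated control trait, and runs the Spearman scan with
Benjamini-Hochberg adjustment across the trait family.
"""

import numpy as np

from rohscan.synthetic_data import SimConfig, simulate_genotypes, simulate_trait
from rohscan.trait_assoc import froh_trait_scan, scan_to_frame

cfg = SimConfig(n_samples=500, n_chrom=2, snps_per_chrom=300,
                trait_model="froh_linear", var_polygenic=0.0, seed=7)
gm, truth = simulate_genotypes(cfg)
# calibrate the effect so the rank correlation lands near the ~0.18 scale
# reported for albumin-to-creatinine ratio in strongly autozygous cohorts
cfg.beta_effect = 0.2 * np.sqrt(cfg.var_noise) / truth.true_fraction.std()
frame = simulate_trait(cfg, gm, truth, trait_name="ACR_like")
frame["control"] = np.random.default_rng(1).normal(size=len(frame))
frame["froh"] = truth.true_fraction

results = froh_trait_scan(frame, ["ACR_like", "control"])
print(scan_to_frame(results).to_string(index=False))
print("\nThe planted trait shows a positive rho with an adjusted p far below"
      "\n0.05; the control trait does not survive the BH correction.")
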