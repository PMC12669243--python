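"""One-command end-to-end demo.

Generates a synthetic cohort with a planted regional-autozygosity effect,
runs the whole pipeline (QC, LD pruning, PCA, GRM, ROH calling, F_ROH trait
correlation, the mixed-model regional scan, clumping, and additive/recessive
validation), writes every output table under ``rohscan_demo/``, and prints
where the top association landed relative to the planted causal region.

Equivalent shell command: ``rohscan demo``.
"""

from rohscan.pipeline import run_demo

result = run_demo(out_dir="rohscan_demo", seed=7)
print(f"\noutput tables: {sorted(p.name for p in result.out_dir.iterdir())}")
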