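# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## ROH calling

The caller is the classic sliding-window scheme. For one sample and one
chromosome, every window of `window_snp = 50` consecutive SNPs *passes* if
it contains at most `window_het_max = 1` heterozygous and
`window_missing_max = 5` missing calls. A SNP's hit fraction is the share
of windows containing it that pass (windows live in SNP-index space, never
span chromosomes, and chromosome-edge SNPs are judged on the fewer windows
that contain them; a chromosome shorter than the window is scanned with a
single truncated window). A SNP is *eligible* when its fraction is ≥
`window_threshold = 0.05` (inclusive comparison). Maximal runs of
consecutive eligible SNPs are split where the gap between adjacent SNPs
exceeds `max_gap_kb = 1000`, and a run is emitted as a segment when it has
≥ `min_snp = 100` SNPs, length ≥ `min_kb = 1000` (1-based inclusive:
length = pos₂ − pos₁ + 1) and density ≤ `max_density_kb_per_snp = 50`.

Two dialect points that surprise users: there is **no** cap on the
heterozygote count within a final segment — only the per-window cap applies
— and segment bounds are the first/last eligible SNP positions, so a
segment can begin a few SNPs inside the homozygous tract that produced it.
These defaults mirror the widely used `--homozyg` dialect and are frozen in
`ROHParams` so the whole dialect is one overridable object.

Correctness is established against a literal brute-force re-implementation
(`rohscan.reference`) that enumerates every window explicitly: the suite
checks exact agreement of eligibility flags and emitted segments on 200
random ≤500-SNP instances with randomised caller parameters.

Cohort summaries classify samples at a single `long_cutoff_kb = 1600`
(none / only ≤1.6 Mb / any >1.6 Mb); carrier percentages are rounded to one
decimal. A sample is a *carrier* of an enriched region when its ROH covers
at least one SNP of the region — the same semantics as the per-SNP
inclusion matrix; a stricter all-SNPs rule is exercised in the tests for
comparison. F_ROH divides total segment length by `genome_length_bp`
(3×10⁹ for real autosomal data; the simulated genome length for synthetic
cohorts — the correlation-based checks are scale-invariant).

## Quality control

Filters run in a fixed, reported order: variant missingness > 0.02 →
sample missingness > 0.1 → HWE exact p ≤ 5×10⁻⁸ → heterozygosity outside
mean ± 3 SD → MAF < 0.05. The HWE test is the two-sided exact conditional
(Levene–Haldane) test without mid-p correction, computed with the standard
ratio recurrence in doubles and validated against an exact-rational
(`fractions.Fraction`) enumerator for every genotype table with N ≤ 25.
The heterozygosity statistic is observed het calls over non-missing calls,
computed on MAF-eligible variants before their removal, with mean/SD
computed once per invocation (not iterated) — re-applying QC can therefore
remove further heterozygosity outliers, which the report makes visible.
MAF uses non-missing calls only.

## Population structure

LD pruning follows the 50-SNP/5-SNP/r² > 0.2 windowed greedy rule; within a
window the worst (highest-r²) pair loses its lower-MAF member, with ties
broken toward the later variant in map order — the reference tool's
internal tie-breaking is undocumented, so exact concordance with it is a
non-goal. r² is the squared Pearson correlation of dosages on
pairwise-complete samples (composite LD; no phasing). PCA mean-imputes
missing calls, standardises by √(2p(1−p)) and eigendecomposes the sample
covariance; components are unit-norm score vectors with eigenvalue/trace
variance fractions. The GRM is the VanRaden form ZZᵀ/Σ2pⱼ(1−pⱼ) on
column-centred dosages, monomorphic variants excluded. PCA and the GRM
spectrum describe the same structure up to per-variant weighting, and the
tests confirm top-axis agreement under strong stratification.

## The regional mixed model

The trait model is y = Xβ + s b + g + ε with X = (1, PC1, PC2, sex, age),
s the per-SNP regional-status column, g ~ N(0, σ²_g K) and ε ~ N(0, σ²_e I).
Estimation is two-stage:

1. **Null fit.** K is eigendecomposed once; the restricted likelihood is
   profiled over h² = σ²_g/(σ²_g + σ²_e) on [0, 1) by bounded scalar
   minimisation (xatol 1e-10), with the h² = 0 boundary checked explicitly;
   fixed effects and the overall scale come from GLS at the optimum.
2. **Per-SNP tests.** Each status column is rotated and whitened by the
   null-fit weights σ²_g λᵢ + σ²_e, residualised against the whitened
   covariates (Frisch–Waugh), and Wald-tested with the residual *scale*
   re-estimated per SNP and a t reference with n − p − 1 df. Holding the
   variance *ratio* (not the scale) fixed makes the test collapse exactly
   to OLS when K = I, which the tests assert to 1e-6.

The two-stage approximation is validated against a per-SNP exact REML
refit oracle (each SNP in the REML design, components re-estimated): p
agrees within 10% relative error on structured-kinship fixtures. Sample
filtering precedes everything: zero-ROH samples are removed first, then
status columns below 1% frequency on the remaining samples. Bonferroni
uses the *computed* number of surviving tests (α/m), never a hard-coded
threshold. Clumping is greedy: most significant unassigned SNP with
p ≤ 1e-4 indexes a clump and absorbs unassigned SNPs within 250 kb with
p ≤ 0.01 and r² > 0.5 against it; p-ties break on variant id so the result
is order-independent. Genotype validation re-tests top signals by OLS with
additive (dosage) and recessive (1 iff dosage = 2) encodings,
complete-case, requiring ≥10 complete cases and a non-constant regressor.
Sex is coded 0/1 (female/male); traits are not rank-transformed.

## Synthetic cohorts

The generator plants autozygosity directly: per sample, a
Poisson(`segment_rate`) number of segments with shifted-exponential lengths
(`min_bp` + Exp(`mean_bp − min_bp`)) are placed uniformly (truncated at
chromosome ends, merged if overlapping); inside a segment one haplotype is
drawn per site from the allele frequency and duplicated, outside genotypes
follow Hardy–Weinberg. Every call is then corrupted to heterozygous with
probability `genotype_error_rate` and set missing with probability
`missing_rate` — spurious heterozygosity is the error mode that breaks ROH
calling, which is why it is the one modelled. Defaults (200 samples, 10
chromosomes × 2000 SNPs at 15 kb mean spacing ≈ a 300 Mb genome;
MAF uniform on [0.05, 0.5]; rate 4 segments of mean 3.5 Mb ⇒ expected
planted fraction ≈ 4.7%; error 10⁻³, missingness 5×10⁻³) are sized so the
planted autozygous fraction matches the ~0.045 mean F_ROH scale of strongly
isolated human cohorts while keeping every planted segment comfortably
above the caller's minimums.

Traits add β_age·age (age ~ U(18, 80), β_age = 0.01/yr) and β_sex·sex
(0.2), an optional causal term, a polygenic draw N(0, var_polygenic·K) with
var_polygenic = 0.2, and noise with var_noise = 1. Causal terms: linear in
the true autozygous fraction (`froh_linear`); β times carrier status of a
causal position for `regional` (the position covered by the most planted
segments, so the regressor is non-degenerate at modest N; the truth record
stores both the intersection interval, on which status is exact, and the
carrier union span — the planted locus); or β times the homozygote
indicator at a causal variant for `recessive` (chosen nearest MAF 0.40,
inside the allele-frequency range observed for recessively acting variants
in isolate studies and where the additive/recessive model contrast is most
identifiable — a design-time power analysis, not a fit to data). Causal
terms use the pre-error, pre-missing truth genotypes so the planted effect
stays well-defined under noise. `effect_size_for_variance` converts a
target variance fraction f into β via β²Var(s) = f/(1−f)·(var_polygenic +
var_noise).

What the generator does **not** emulate: linkage disequilibrium between
variants (sites are independent given the planted segments), pedigree- or
coalescent-accurate segment sharing between individuals (background
relatedness enters only through the polygenic trait term, so the GRM of a
synthetic cohort is near-identity), allele-frequency spectra below 5%, and
chromosome X. Passing tests therefore demonstrate the statistical
machinery — calling, calibration, power, encoding contrasts — not
robustness to real LD structure or platform artefacts.

## Validation experiment sizes

`rohscan.experiments` fixes the problem sizes used by the acceptance suite
and script: segment recovery on an error-free 200×20,000 cohort
(bp-Jaccard of called vs planted intervals, pooled over the cohort, and the
F_ROH–truth correlation); type-I error over 20 independent N=300 cohorts ×
500 evenly-spaced status columns (≥10,000 tests), judged with the
between-cohort (clustered) standard error because status columns within a
cohort are spatially correlated — the plain binomial SE would overstate
precision; power over 20 N=500 cohorts with an 8%-variance planted
regional effect, success being min p < 10⁻⁸ inside the planted locus (this
sits near the design's theoretical power ceiling of ~0.8: the causal-column
noncentrality is ≈6.5 against the ≈5.8 needed, so individual replications
of the power experiment fluctuate around the 0.80 line); and the
recessive-vs-additive contrast over 50 N=500 cohorts at a 0.5-SD purely
recessive effect. The two-stage scheme shows the expected mild
anticonservativeness (empirical size a few thousandths above α), within
three clustered SEs of 0.05.

## Known limitations

* The LD-pruning greedy rule is deterministic but not guaranteed identical
  to any particular external tool's internal tie-breaking.
* The two-stage LMM slightly understates per-SNP uncertainty relative to a
  full per-SNP REML refit (bounded at 10% relative p error in the tests).
* With a near-identity GRM (unrelated synthetic cohorts), h² is weakly
  identified; the null-fit h² estimate is noisy even though the per-SNP
  tests remain calibrated.
* Carrier counting for enriched regions uses the any-SNP rule; an
  all-SNPs rule gives smaller counts on partially overlapping ROH.
* Binary traits, dosages, phased data and chromosome X are out of scope.
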