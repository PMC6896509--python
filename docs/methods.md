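# Methods

This note records the models, the simulation design, the numerical
choices, and the limitations of `seqblup`.  Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Models

### Mixed-model GWAS (discovery stage)

Per sequence variant i with dosage vector sᵢ ∈ {0,1,2}ⁿ:

    y* = Xb + sᵢαᵢ + ZQq + Zg + e
    q ~ N(0, I σ²q),   g ~ N(0, G σ²g),   e ~ N(0, I σ²e)

y* is the corrected phenotype; X holds the intercept and a data-source
factor; Q holds pedigree breed proportions (plus optional sub-breed
columns, emulating strain structure within one breed); G is the VanRaden
GRM built from the HD panel.  Variance components are estimated once by
REML under the null (no variant term) and held fixed for the scan — the
standard two-stage (EMMAX-type) approximation of per-variant REML, chosen
because a full per-variant REML is orders of magnitude more expensive and
the approximation is accurate when single-variant effects are small.  The
per-variant test is a two-sided Wald test with a Gaussian reference; the
exact per-variant GLS is verified against a dense-matrix oracle to 1e-8
relative in the tests.

Computation: with G = U D Uᵀ, all vectors are rotated by Uᵀ once; the
low-rank breed term is handled by the Woodbury identity, so the null REML
is a three-parameter bounded quasi-Newton optimization (multi-start, with
a derivative-free polish if the line search aborts) and the scan costs
O(n²) once plus O(n) per variant.

### Variant selection

Windows of 100 kb sliding by 50 kb from position 1 of each chromosome
(1-based, inclusive); per window the smallest p-value below 1e-3 wins,
with ties broken to the smaller position then the smaller identifier.
Duplicate wins from overlapping windows collapse to one entry.  Greedy LD
pruning in ascending p order removes a candidate whose r² with any
retained same-chromosome candidate exceeds 0.95 (the more significant of
a pair survives; pruning r² is computed in the discovery genotypes).
Candidates with training-set MAF strictly below 0.005 are removed (a
variant at exactly 0.005 is kept).  Every removal is recorded with its
reason, so candidate counts always reconcile.  When the top set is fitted
alongside the array panel, overlapping variants are moved out of the
array panel and kept as top SNPs; the array panel is used intact when
fitted alone.

### GREML / GBLUP

    y = 1μ + Σⱼ Zuⱼ + e,   uⱼ ~ N(0, Gⱼ σ²gj)

with k = 1 (any single panel) or k = 2 (array + top SNPs).  GRMs are
VanRaden method 1, G = WWᵀ / (2Σpⱼ(1−pⱼ)), dosages centred by twice the
observed allele frequency of the sample set at hand and missing calls
mean-imputed.  REML uses average-information updates after three EM
warm-up steps, step-halving on any likelihood decrease, estimates floored
at 1e-6·var(y) (components are never dropped, keeping k stable), and
convergence at |Δ log L| < 1e-8 within 200 iterations; a stall in which
no step improves the likelihood is treated as numerical convergence.
With a single genomic component the restricted likelihood is instead
maximized exactly in the eigenbasis of G (a 2-parameter problem).  GRMs
receive a 1e-6 diagonal jitter before factorization.

Prediction is BLUP at the estimated ratios: uⱼ = σ²gj Gⱼ[·,train] P y
for training and target rows alike, with P the REML projection absorbing
the intercept; the overall GBV is the component sum.  GBLUP with a
VanRaden GRM is verified to equal SNP-BLUP ridge regression (λ =
2Σpq·σ²e/σ²g, joint mixed-model equations) to 1e-6 on an n=300, m=1,000
instance.  Heritability per component is σ²gj / (Σσ²g + σ²e); the total
is the component sum.

### BayesR / BayesRC

Standardized genotypes (training mean and SD; targets transformed with
training statistics; missing → 0 after centring).  Effects follow a
four-class zero-mean normal mixture with variances (0, 1e-4, 1e-3, 1e-2)
× σ²g, where σ²g is resampled each iteration, making the scales relative.
Gibbs updates per iteration: intercept; per SNP the class (effect
marginalized) then the effect given the class, with the residual vector
maintained incrementally; mixing proportions from Dirichlet(1+counts) —
per category for BayesRC, the only difference between the methods; σ²g
and σ²e from scaled-inverse-χ² conditionals with ν₀ = 4 and scale
0.5·var(y) (weakly informative conjugate choices; sampling σ²g rather
than fixing it is a deliberate design choice).  SNPs are updated in fixed
genome order for reproducibility; every 10th post-burn-in draw is kept.
Per-iteration h² is var(Xβ)/(var(Xβ)+σ²e) over training samples.  The
kernel is numba-compiled; chains are seeded independently (seed +
1000003·chain) and exactly reproducible.  Defaults are 5 chains of
40,000 iterations with 20,000 burn-in; tests and examples run scaled-down
chains and label them as such.  Single-category BayesRC reduces bit-for-
bit to BayesR; a degenerate single-class mixture with fixed variances
matches ridge regression within 5% relative RMSE.

Known behaviour worth stating: under a *true null* phenotype the class
labels are only weakly identified — σ²g collapses, the small-variance
classes merge with the null class, and the posterior mixing vector stays
diffuse rather than concentrating on the null class.  The quantities that
are identified (posterior h², held-out predictive correlation) do go to
zero, and those are what the null tests assert.

### Study design and evaluation

The per-trait split draws ~30% of phenotyped animals (breed-stratified,
seeded) for discovery; validation candidates come only from designated
breed groups (a purebred group and the F1 cross) and are drawn whole
paternal half-sib families at a time, so no family spans training and
validation; remaining family members outside the validation groups are
set aside rather than trained on.  Candidates whose recorded sire is in
training, or whose maximum genomic relationship to any training animal
reaches the threshold (default 0.25; 0.125 is the wool-trait
convention), are excluded — validation size is sacrificed, never the
threshold — and every exclusion is audited.  Maternal half-sibs are not
constrained (sire-based families only).  Pre-correction fits the GWAS
null model and removes X b̂ and Q q̂ from the phenotype; the polygenic
BLUP is left in.  Re-applying the correction changes phenotypes only at
the 1e-6 level (exact idempotence is impossible when variance components
are re-estimated).

Accuracy is r(GBV, y*)/√h²_ref with h²_ref always the training-set
single-GRM GREML heritability of the array panel, for every method, so
scenarios differ only in the correlation; bias is the OLS slope of y* on
GBV; Bayesian scenarios are scored per chain and averaged.  The scenario
grid spans eleven models: GBLUP on top / array / array+top (one GRM) /
HD / sequence panels, the two-GRM model, BayesR on four panels, and
BayesRC on array+top.  A sequence-panel Bayesian fit is deliberately out
of scope.

## Synthetic data

The generator emulates the structure the method depends on, not sheep
biology per se:

* **Breed divergence** — Balding–Nichols: per breed, allele frequencies
  drawn Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p, F = F_ST
  (default 0.10, a typical between-breed value for livestock).  One breed
  can be split into extra-drifted sub-groups (strain structure).
* **LD** — founder-haplotype block copying: each gamete copies one of 30
  founder haplotypes per 50-kb block, and offspring gametes recombine
  parental haplotypes at block boundaries.  This yields high within-block
  r², background r² ≈ 1/n across blocks, and genuine genome sharing along
  recorded sire/dam links (half-sib families of ~10).  It is not a
  coalescent model: no mutation, no recombination within blocks, no
  realistic allele-frequency spectrum.
* **Panels** — array and HD panels are near-uniformly spaced subsets of
  the sequence set (defaults 400 ⊂ 1,200 ⊂ 3,000 at unit-test scale;
  sizes are configurable), so panel nesting mirrors real chip design.
* **Trait** — a configurable number of QTL drawn from the sequence set
  with 30% forced off the array by default (the premise that gives
  selected sequence variants room to help); effects from a BayesR-style
  scale mixture; one categorical fixed effect ("data source") stands in
  for contemporary-group corrections; residual noise scaled so realized
  h² approaches the target (defaults 0.30–0.40, mid-range of the
  meat/wool traits that motivate the pipeline, which span roughly
  0.07–0.68).  True breeding values, per-variant effects and causal flags
  are returned for recovery tests.

All randomness flows from a single seeded generator; identical
configurations are bit-identical.  What passing tests show is therefore
that the *statistical machinery* is correct and that the selected-variant
mechanism behaves as expected when its premise holds; they cannot show
that real sheep data satisfy the premise (imputation error, maternal
effects, genotype-by-environment structure and multi-generation pedigrees
are all absent from the simulator).

## Problem sizes

Chosen as the package's standard desk-scale operating points: oracle
equivalences at n = 120–300; parameter recovery at n = 1,000–1,500 with
m = 1,000–2,000 variants (20 phenotype replicates for GREML, 3 simulation
replicates for two-GRM GREML and BayesR); GWAS calibration with 5,000
null variants and power at n = 2,000 over 25–50 replicates; the headline
direction over 20 end-to-end replicates of a 650-animal, 2,000-variant
population per condition, with single-chain 2,000-iteration MCMC.  The
acceptance script runs one 780-animal pipeline with 2 chains × 4,000
iterations plus the recovery and calibration blocks.

## File formats

PLINK1 SNP-major `.bed/.bim/.fam` (dosage counts the A1 allele; 2-bit
codes 00→2, 01→missing, 10→1, 11→0, samples packed four per byte
LSB-first), GCTA `.grm.bin` (float32 lower triangle, row-major, diagonal
included) with `.grm.id`, and tab-separated UTF-8 tables with `.` for
missing values.  Coordinates are 1-based inclusive.  Round trips are
exact for genotypes and ≤ 1e-6 for float32 GRMs; panel nesting
(array ⊆ HD ⊆ sequence) is enforced on load.

## Limitations

* Hard-call genotypes only; no VCF/BGEN, no imputation dosages, no
  X/Y/MT handling.
* The GWAS reuses null-model variance components for every variant; a
  per-variant REML would differ slightly for large-effect variants.
* No leave-one-chromosome-out GRMs in the scan (proximal contamination
  slightly deflates power near large QTL).
* Negative variance estimates are floored, not removed; approximate
  reliabilities from MME inverses are not computed.
* Accuracy standard errors are not bootstrapped; replicate runs of the
  pipeline are the intended way to gauge uncertainty.
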