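# seqblup

Genomic prediction with sequence variants selected from an independent
GWAS, for multi-breed and crossbred livestock populations.

## The problem

Standard genomic selection predicts an animal's additive genetic merit
(its genomic breeding value, GBV) from a medium-density SNP array — in
sheep, a "50k" chip — using GBLUP with a genomic relationship matrix
(GRM).  In diverse multi-breed populations the linkage disequilibrium
between array markers and causal variants is weak, especially across
breeds, so accuracy is low precisely for the animals that are least
related to the reference data.  Whole-genome sequence carries variants at
or near the causal mutations, but fitted wholesale it adds almost nothing:
the signal drowns in millions of uninformative markers.

The strategy this package implements and tests end-to-end: run a
mixed-model GWAS on sequence genotypes in an *independent* discovery set,
keep the most significant variant per 100-kb sliding window below
p < 1e-3, prune pairs with r² > 0.95, drop variants with training-set
MAF < 0.005, and give the surviving "top SNPs" their own variance in the
prediction model — either as a second GRM in GBLUP ("2GBLUP"),

    y = 1μ + Zu₁ + Zu₂ + e,   u₁ ~ N(0, G₁σ²g1),  u₂ ~ N(0, G₂σ²g2),

or as a separate category in BayesRC, the BayesR four-class normal-mixture
model (class variances 0, 1e-4, 1e-3, 1e-2 × σ²g on standardized
genotypes) with independent mixing proportions per variant category.
Accuracy is judged in validation sets deliberately unrelated to training
(no shared paternal half-sib families, no sires, genomic relationships
below a threshold) as r(GBV, y*)/√h², with bias as the regression of the
corrected phenotype y* on GBV.

Real multi-breed sheep datasets of this kind are not publicly deposited,
so the package ships a first-class synthetic-data generator
(`seqblup.synthetic_data`) that reproduces the statistical structure the
method needs: Balding–Nichols breed divergence, local LD from founder
haplotype blocks, paternal half-sib families, nested array ⊂ HD ⊂ sequence
panels, and a configurable fraction of causal variants absent from the
array.

## Worked example

`examples/05_full_pipeline.py` runs the whole study on a simulated
population (650 animals, 2,000 sequence variants, 30% of causal variants
off-array, MCMC scaled down to 2 chains × 2,000 iterations):

```
top SNPs selected: 2; reference h2 (array GREML): 0.457

            method    group  n  accuracy  bias  delta_vs_benchmark
         GBLUP-50k       B0 60     0.214 0.382               0.000
         GBLUP-50k F1_B1xB0 52     0.286 0.552               0.000
            2GBLUP       B0 60     0.603 0.817               0.389
            2GBLUP F1_B1xB0 52     0.437 0.760               0.151
           BayesRC       B0 60     0.464 0.736               0.249
           BayesRC F1_B1xB0 52     0.456 0.854               0.169
  ...                                     (11 scenarios in total)
```

Each row is one prediction scenario in one validation group (`B0` a
purebred group, `F1_B1xB0` the crossbred group): `accuracy` is the
heritability-scaled correlation, `bias` the regression slope (1 =
unbiased), and `delta_vs_benchmark` the accuracy change relative to
array-panel GBLUP.  Fitting the selected variants as their own component
(2GBLUP, BayesRC) improves accuracy markedly, because part of the causal
signal is absent from the array and enters only through the top SNPs.
The other examples walk through the individual stages: simulation and LD
structure (01), study design and the discovery GWAS (02), GREML/GBLUP
with one and two components (03), and BayesR/BayesRC (04).

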