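"""BayesR and BayesRC on a simulated trait (scaled-down MCMC settings).

Fits the four-class normal-mixture model to training genotypes and shows
the posterior heritability, the mixing proportions, and how BayesRC's
separate category for 'top' variants concentrates non-null mass where the
causal enrichment is.  Production analyses use 5 chains x 40,000
iterations; this demo runs 2 x 3,000 to stay interactive.
"""

import numpy as np

import seqblup as sb
from seqblup import bayesr as br

cfg = sb.SimulationConfig(
    seed=4, n_per_group={"B0": 400, "B1": 300}, n_seq_variants=1200,
    n_hd_variants=1200, n_array_variants=400, n_qtl=50, h2=0.4)
g, samples, truth = sb.simulate_population(cfg)
train = g.samples[:550]
valid = g.samples[550:]
# pre-adjust for the data-source fixed effect, as the pipeline does upstream
d = np.asarray(
    np.column_stack([samples.df["data_source"] == s
                     for s in samples.df["data_source"].unique()]), float)
y = samples.df["phenotype"].to_numpy(float)
y = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
y_train = y[:550]

mask = g.subset(sample_ids=train).maf() >= 0.005
std = br.standardize(g, train, variant_mask=mask)

model = br.bayesr_fit(y_train, std.matrix(train), std.variant_ids,
                      n_iter=3000, n_burnin=1500, n_chains=2, seed=4)
h2 = br.bayes_heritability(model)
print(f"BayesR posterior h2: {h2['mean']:.3f} "
      f"(chains: {[round(x, 3) for x in h2['per_chain']]}; "
      f"true realized {truth.realized_h2:.3f})")
print("mixing proportions (null, 1e-4, 1e-3, 1e-2 x sigma_g^2):",
      np.round(model.chains[0].pi_mean[0], 3))
rhat = br.gelman_rubin([c.h2_samples for c in model.chains])
print(f"h2 Gelman-Rubin R-hat across chains: {rhat:.3f} (< 1.1 is converged)")

# BayesRC: causal-enriched category vs the rest
causal_ids = set(truth.causal[truth.causal].index)
cats = {v: ("top" if v in causal_ids else "array") for v in std.variant_ids}
rc = br.bayesrc_fit(y_train, std.matrix(train), std.variant_ids, cats,
                    n_iter=3000, n_burnin=1500, n_chains=2, seed=5)
labels = rc.category_labels
nn = 1.0 - np.mean([c.pi_mean[:, 0] for c in rc.chains], axis=0)
print("\nBayesRC non-null mixing mass by category:")
for lab, v in zip(labels, nn):
    print(f"  {lab:>6}: {v:.3f}")
gbv = br.bayes_predict(rc, std.matrix(valid))
r = np.corrcoef(gbv["gbv_mean"], y[550:])[0, 1]
print(f"validation correlation of BayesRC GBV with phenotype: {r:.3f}")
print("\nThe enriched category keeps a much larger non-null proportion, so"
      "\nits variants are shrunk less - the mechanism that lets selected"
      "\nsequence variants add accuracy on top of an array panel.")
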