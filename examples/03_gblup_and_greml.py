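"""GREML heritability and GBLUP prediction, one and two variance components.

Fits the array-panel GREML (the industry benchmark), then adds the true
causal variants as a second relationship matrix — the idealized version of
the '50k + top SNPs, two GRMs' model — and compares validation accuracy.
"""

import numpy as np

import seqblup as sb
from seqblup import evaluation
from seqblup.greml_gblup import gblup_predict, greml, heritability
from seqblup.grm import compute_grm

cfg = sb.SimulationConfig(
    seed=3, n_per_group={"B0": 500, "B1": 300}, n_seq_variants=1500,
    n_hd_variants=600, n_array_variants=250, n_qtl=60, h2=0.35,
    qtl_off_array_frac=0.30)
g, samples, truth = sb.simulate_population(cfg)

rng = np.random.default_rng(0)
perm = rng.permutation(g.n_samples)
train = [g.samples[i] for i in perm[:600]]
valid = [g.samples[i] for i in perm[600:]]
y = samples.df.set_index("sample_id")["phenotype"]
y_train = y.loc[train].to_numpy()

grm_array = compute_grm(g, "ARRAY50K", 0.005)
vc1 = greml(y_train, [grm_array], sample_ids=train)
h1 = heritability(vc1)
print(f"array GREML: h2 = {h1['total']:.3f} "
      f"(sigma_g={list(vc1.components.values())[0]:.4f}, "
      f"sigma_e={vc1.sigma_e2:.4f}, {vc1.n_iter} iterations)")

causal = truth.causal.to_numpy()
grm_causal = compute_grm(g, "causal", 0.0, variant_mask=causal)
vc2 = greml(y_train, [grm_array, grm_causal], sample_ids=train)
h2 = heritability(vc2)
print(f"two-GRM GREML: h2 = {h2['total']:.3f} "
      f"(array {h2['array' if 'array' in h2 else 'ARRAY50K']:.3f}"
      f" + causal {h2['causal']:.3f})")

fit1 = gblup_predict(y_train, vc1, [grm_array], train, valid)
fit2 = gblup_predict(y_train, vc2, [grm_array, grm_causal], train, valid)
y_valid = y.loc[valid]
for label, fit in (("GBLUP (array)", fit1), ("2GBLUP (array+causal)", fit2)):
    gbv = fit.gbv.loc[valid, "gbv_total"]
    acc = evaluation.accuracy(gbv, y_valid, h1["total"])
    slope = evaluation.bias(gbv, y_valid)
    print(f"{label:>22}: accuracy {acc:.3f}  bias slope {slope:.2f}")
print("\nThe second component lets the causal variants carry their own"
      "\nvariance instead of being shrunk with the array markers, which"
      "\nraises validation accuracy; a slope of 1 means unbiased GBVs.")
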