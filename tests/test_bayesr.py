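"""BayesR/BayesRC Gibbs sampler behaviour."""

import numpy as np
import pytest

import seqblup as sb
from seqblup.bayesr import (MixtureSpec, bayes_heritability, bayes_predict,
                            bayesr_fit, bayesrc_fit, gelman_rubin, standardize)

from conftest import make_genotypes


def std_design(n, m, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    return (X - X.mean(0)) / X.std(0), rng


class TestStandardize:
    def test_unit_variance_columns(self):
        g = make_genotypes(90, 40, seed=1)
        ids = g.samples[:60]
        std = standardize(g, ids)
        X = std.matrix(ids)
        assert np.allclose(X.mean(0), 0, atol=1e-12)
        assert np.allclose(X.var(0), 1, atol=1e-12)

    def test_targets_use_training_statistics(self):
        g = make_genotypes(90, 40, seed=1)
        std = standardize(g, g.samples[:60])
        Xt = std.matrix(g.samples[60:])
        manual = (g.dosage[60:].astype(float) - std.mean) / std.sd
        assert np.allclose(Xt, manual)

    def test_constant_column_names_variant(self):
        g = make_genotypes(50, 5, seed=2)
        g.dosage[:, 3] = 1
        with pytest.raises(ValueError, match="v3"):
            standardize(g, g.samples)

    def test_effects_backtransform_reproduces_gbv(self):
        # b_std on the standardized scale == b_dosage * sd: GBVs agree exactly
        g = make_genotypes(80, 30, seed=3)
        std = standardize(g, g.samples)
        rng = np.random.default_rng(0)
        b_std = rng.standard_normal(30)
        gbv_std = std.matrix(g.samples) @ b_std
        b_dosage = b_std / std.sd
        gbv_dosage = (g.dosage.astype(float) - std.mean) @ b_dosage
        assert np.abs(gbv_std - gbv_dosage).max() < 1e-10


class TestBayesR:
    def test_null_phenotype_low_h2_and_no_prediction(self):
        X, rng = std_design(500, 200, 1)
        y = rng.standard_normal(500)
        vids = [f"v{j}" for j in range(200)]
        model = bayesr_fit(y, X, vids, n_iter=5000, n_burnin=2500,
                           n_chains=1, seed=2)
        assert bayes_heritability(model)["mean"] < 0.05
        Xt, _ = std_design(200, 200, 9)
        yt = np.random.default_rng(10).standard_normal(200)
        gbv = bayes_predict(model, Xt)["gbv_mean"]
        r2 = np.corrcoef(gbv, yt)[0, 1] ** 2
        assert r2 < 0.05

    def test_large_qtl_assigned_to_top_class(self):
        X, rng = std_design(500, 1000, 4)
        beta = np.zeros(1000)
        beta[123] = 1.0
        gvec = X @ beta
        y = gvec + rng.normal(0, np.sqrt(gvec.var() * 1.5), 500)  # ~40% var
        vids = [f"v{j}" for j in range(1000)]
        model = bayesr_fit(y, X, vids, n_iter=4000, n_burnin=2000,
                           n_chains=1, seed=5)
        assert model.class_prob[123, 3] > 0.9
        assert model.beta_mean[123] == pytest.approx(1.0, rel=0.2)

    def test_degenerate_single_class_matches_ridge(self):
        X, rng = std_design(200, 80, 6)
        beta_true = rng.normal(0, 0.15, 80)
        y = X @ beta_true + rng.normal(0, 1.0, 200)
        c, s2g, s2e = 0.02, 1.0, 1.0
        spec = MixtureSpec(variance_scales=(c,))
        model = bayesr_fit(y, X, [f"v{j}" for j in range(80)], spec=spec,
                           n_iter=8000, n_burnin=2000, n_chains=1, seed=7,
                           fix_s2g=s2g, fix_s2e=s2e)
        lam = s2e / (c * s2g)
        yc = y - y.mean()
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(80), X.T @ yc)
        rmse = np.sqrt(np.mean((model.beta_mean - ridge) ** 2))
        assert rmse / np.sqrt(np.mean(ridge ** 2)) < 0.05

    def test_all_zero_scales_give_zero_gbv(self):
        X, rng = std_design(100, 50, 8)
        y = rng.standard_normal(100)
        spec = MixtureSpec(variance_scales=(0.0,), dirichlet_prior=(1.0,))
        model = bayesr_fit(y, X, [f"v{j}" for j in range(50)], spec=spec,
                           n_iter=500, n_burnin=100, n_chains=1, seed=9)
        gbv = bayes_predict(model, X)
        assert np.all(gbv["gbv_mean"] == 0.0)

    def test_seeded_chains_reproducible(self):
        X, rng = std_design(150, 60, 10)
        y = rng.standard_normal(150)
        vids = [f"v{j}" for j in range(60)]
        a = bayesr_fit(y, X, vids, n_iter=800, n_burnin=400, n_chains=2, seed=3)
        b = bayesr_fit(y, X, vids, n_iter=800, n_burnin=400, n_chains=2, seed=3)
        for ca, cb in zip(a.chains, b.chains):
            assert np.array_equal(ca.beta_mean, cb.beta_mean)
            assert np.array_equal(ca.h2_samples, cb.h2_samples)

    def test_chains_agree_gelman_rubin(self):
        X, rng = std_design(300, 300, 11)
        beta = rng.normal(0, 0.1, 300) * (rng.random(300) < 0.05)
        gvec = X @ beta
        y = gvec + rng.normal(0, max(gvec.std(), 0.3) * 1.2, 300)
        model = bayesr_fit(y, X, [f"v{j}" for j in range(300)], n_iter=4000,
                           n_burnin=2000, n_chains=3, seed=12)
        for attr in ("s2g_samples", "s2e_samples", "h2_samples"):
            r = gelman_rubin([getattr(c, attr) for c in model.chains])
            assert r < 1.1

    def test_class_probabilities_simplex(self):
        X, rng = std_design(100, 40, 13)
        y = rng.standard_normal(100)
        model = bayesr_fit(y, X, [f"v{j}" for j in range(40)], n_iter=600,
                           n_burnin=300, n_chains=1, seed=14)
        assert np.allclose(model.class_prob.sum(axis=1), 1.0, atol=1e-9)
        c = model.chains[0]
        assert np.allclose(c.pi_samples.sum(axis=2), 1.0, atol=1e-9)

    def test_invalid_iteration_counts_rejected(self):
        X, _ = std_design(10, 5, 0)
        with pytest.raises(ValueError, match="exceed"):
            bayesr_fit(np.zeros(10), X, list("abcde"), n_iter=100, n_burnin=100)


class TestBayesRC:
    def test_single_category_reduces_to_bayesr(self):
        X, rng = std_design(150, 60, 20)
        y = rng.standard_normal(150)
        vids = [f"v{j}" for j in range(60)]
        a = bayesr_fit(y, X, vids, n_iter=800, n_burnin=400, n_chains=1, seed=6)
        b = bayesrc_fit(y, X, vids, {v: "all" for v in vids}, n_iter=800,
                        n_burnin=400, n_chains=1, seed=6)
        assert np.array_equal(a.beta_mean, b.beta_mean)

    def test_identical_architectures_give_matching_proportions(self):
        X, rng = std_design(400, 400, 21)
        beta = rng.normal(0, 0.15, 400) * (rng.random(400) < 0.05)
        gvec = X @ beta
        y = gvec + rng.normal(0, max(gvec.std(), 0.2), 400)
        vids = [f"v{j}" for j in range(400)]
        cats = {v: ("A" if j < 200 else "B") for j, v in enumerate(vids)}
        model = bayesrc_fit(y, X, vids, cats, n_iter=4000, n_burnin=2000,
                            n_chains=1, seed=22)
        c = model.chains[0]
        # overlapping 90% intervals of non-null mass per category
        nn = 1.0 - c.pi_samples[:, :, 0]
        lo_a, hi_a = np.percentile(nn[:, 0], [5, 95])
        lo_b, hi_b = np.percentile(nn[:, 1], [5, 95])
        assert lo_a <= hi_b and lo_b <= hi_a

    def test_enriched_category_gets_more_non_null_mass(self):
        wins = 0
        reps = 6
        for rep in range(reps):
            X, rng = std_design(400, 500, 30 + rep)
            vids = [f"v{j}" for j in range(500)]
            # category A: first 100 variants, 10x enriched for QTL
            qtl_a = rng.random(100) < 0.20
            qtl_b = rng.random(400) < 0.02
            beta = np.zeros(500)
            beta[:100][qtl_a] = rng.normal(0, 0.3, qtl_a.sum())
            beta[100:][qtl_b] = rng.normal(0, 0.3, qtl_b.sum())
            gvec = X @ beta
            y = gvec + rng.normal(0, gvec.std(), 400)
            cats = {v: ("A" if j < 100 else "B") for j, v in enumerate(vids)}
            model = bayesrc_fit(y, X, vids, cats, n_iter=3000, n_burnin=1500,
                                n_chains=1, seed=50 + rep)
            c = model.chains[0]
            nn = 1.0 - c.pi_mean[:, 0]
            if nn[0] > nn[1]:
                wins += 1
        assert wins >= reps - 1


class TestPredict:
    def test_zero_effects_zero_gbv(self):
        X, _ = std_design(50, 20, 0)
        spec = MixtureSpec(variance_scales=(0.0,), dirichlet_prior=(1.0,))
        model = bayesr_fit(np.zeros(50) + np.arange(50) * 0.01, X,
                           [f"v{j}" for j in range(20)], spec=spec,
                           n_iter=200, n_burnin=100, n_chains=2, seed=1)
        gbv = bayes_predict(model, X)
        assert (gbv["gbv_mean"] == 0).all()

    def test_chain_average_is_mean_of_chains(self):
        X, rng = std_design(100, 30, 40)
        y = rng.standard_normal(100)
        model = bayesr_fit(y, X, [f"v{j}" for j in range(30)], n_iter=600,
                           n_burnin=300, n_chains=3, seed=2)
        gbv = bayes_predict(model, X)
        chains = gbv[[c for c in gbv.columns if c.startswith("chain")]]
        assert np.allclose(gbv["gbv_mean"], chains.mean(axis=1), atol=1e-12)

    def test_single_nonzero_effect_linear_in_dosage(self):
        X, _ = std_design(50, 3, 1)
        import seqblup.bayesr as br
        model = br.BayesRModel(MixtureSpec(), np.array(["a", "b", "c"]),
                               ["all"], [], 10, 5)
        chain = br.ChainResult(0, np.array([0.0, 2.5, 0.0]),
                               np.zeros((3, 4)), np.zeros((1, 4)),
                               np.zeros(1), np.zeros(1), np.zeros(1),
                               np.zeros((1, 1, 4)))
        model.chains.append(chain)
        gbv = bayes_predict(model, X)
        assert np.allclose(gbv["gbv_mean"], 2.5 * X[:, 1])
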