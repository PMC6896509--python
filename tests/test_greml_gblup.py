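"""GREML variance components and GBLUP prediction."""

import numpy as np
import pytest

import seqblup as sb
from seqblup.greml_gblup import gblup_predict, greml, heritability
from seqblup.grm import compute_grm
from seqblup.gwas import VarianceComponents


def simulate_trait(g, h2, seed, causal_mask=None):
    """Phenotype from the genotype matrix with the requested heritability."""
    rng = np.random.default_rng(seed)
    m = g.n_variants
    mask = np.ones(m, bool) if causal_mask is None else causal_mask
    eff = np.zeros(m)
    eff[mask] = rng.normal(0, 1.0 / np.sqrt(mask.sum()), mask.sum())
    tbv = g.dosage.astype(float) @ eff
    noise = rng.normal(0, np.sqrt(tbv.var() * (1 - h2) / h2), g.n_samples)
    return tbv + noise, tbv


@pytest.fixture(scope="module")
def pop800():
    cfg = sb.SimulationConfig(seed=21, n_per_group={"B0": 500, "B1": 300},
                              n_seq_variants=1200, n_hd_variants=1200,
                              n_array_variants=400, n_qtl=100, h2=0.3)
    return sb.simulate_population(cfg)


class TestGreml:
    def test_single_component_recovery(self, pop800):
        g, s, _ = pop800
        grm = compute_grm(g, "WGS", 0.01)
        ests = []
        for seed in range(5):
            y, _ = simulate_trait(g, 0.3, seed)
            vc = greml(y, [grm])
            ests.append(heritability(vc)["total"])
        assert np.mean(ests) == pytest.approx(0.3, abs=0.05)

    def test_optimum_beats_surrounding_grid(self, pop800):
        g, s, _ = pop800
        grm = compute_grm(g, "WGS", 0.01)
        y, _ = simulate_trait(g, 0.4, 3)
        vc = greml(y, [grm])
        # evaluate the restricted likelihood on a grid around the optimum
        from seqblup.greml_gblup import _neg2ll_single
        G = grm.values + 1e-6 * np.eye(grm.n)
        d, U = np.linalg.eigh(G)
        d = np.clip(d, 0, None)
        yt = U.T @ y
        Xt = U.T @ np.ones((y.size, 1))
        opt = _neg2ll_single(np.log([list(vc.components.values())[0],
                                     vc.sigma_e2]), d, yt, Xt)
        for fg in np.linspace(0.7, 1.3, 5):
            for fe in np.linspace(0.7, 1.3, 4):
                if fg == 1.0 and fe == 1.0:
                    continue
                val = _neg2ll_single(
                    np.log([list(vc.components.values())[0] * fg,
                            vc.sigma_e2 * fe]), d, yt, Xt)
                assert opt <= val + 1e-6

    def test_two_component_total_variance(self, pop800):
        g, s, truth = pop800
        causal = truth.causal.to_numpy()
        grm1 = compute_grm(g, "ARRAY50K", 0.01)
        grm2 = compute_grm(g, "WGS", 0.0, variant_mask=causal)
        grm2.panel_name = "causal"
        y, tbv = simulate_trait(g, 0.4, 11, causal_mask=causal)
        vc = greml(y, [grm1, grm2])
        total_genetic = sum(vc.components.values())
        assert total_genetic == pytest.approx(tbv.var(), rel=0.25)
        assert vc.converged

    def test_duplicated_grm_matches_single_fit(self, pop800):
        g, s, _ = pop800
        grm = compute_grm(g, "ARRAY50K", 0.01)
        y, _ = simulate_trait(g, 0.35, 5)
        vc1 = greml(y, [grm])
        vc2 = greml(y, [grm, grm])
        assert sum(vc2.components.values()) == pytest.approx(
            sum(vc1.components.values()), rel=0.05)
        assert vc2.loglik == pytest.approx(vc1.loglik, abs=1e-3)

    def test_zero_variance_phenotype_rejected(self, pop800):
        g, _, _ = pop800
        grm = compute_grm(g, "ARRAY50K", 0.01)
        with pytest.raises(ValueError, match="variance"):
            greml(np.ones(grm.n), [grm])

    def test_too_many_components_rejected(self, pop800):
        g, _, _ = pop800
        grm = compute_grm(g, "ARRAY50K", 0.01)
        with pytest.raises(ValueError, match="1 to 3"):
            greml(np.zeros(grm.n), [grm] * 4)


class TestGblupPredict:
    def test_near_perfect_heritability_interpolates(self, pop800):
        g, _, _ = pop800
        ids = g.samples[:300]
        grm = compute_grm(g.subset(sample_ids=ids), "WGS", 0.01)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(300)
        vc = VarianceComponents({"WGS": 1.0}, 1e-8, 0.0, True, 1)
        fit = gblup_predict(y, vc, [grm], ids)
        resid = y - fit.mu - fit.gbv["gbv_total"].to_numpy()
        assert np.abs(resid).max() < 1e-4

    def test_equals_snp_blup_ridge(self):
        # GBLUP with a VanRaden GRM == ridge regression on centred dosages
        # with lambda = 2*sum(p q) * s2e/s2g, solved via the joint MME
        cfg = sb.SimulationConfig(seed=31, n_per_group={"B0": 300},
                                  n_seq_variants=1000, n_hd_variants=1000,
                                  n_array_variants=1000, n_qtl=100, h2=0.4)
        g, s, _ = sb.simulate_population(cfg)
        grm = compute_grm(g, "WGS", 0.0)
        tr, tg = list(g.samples[:260]), list(g.samples[260:])
        y = s.df["phenotype"].to_numpy(float)[:260]
        vc = VarianceComponents({"WGS": 0.3}, 0.2, 0.0, True, 1)
        fit = gblup_predict(y, vc, [grm], tr, tg)

        dos = g.dosage.astype(float)
        p = dos.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        W = dos[:, keep] - 2 * p[keep]
        lam = 2 * np.sum(p[keep] * (1 - p[keep])) * 0.2 / 0.3
        Wt, m = W[:260], keep.sum()
        ones = np.ones((260, 1))
        A = np.block([[ones.T @ ones, ones.T @ Wt],
                      [Wt.T @ ones, Wt.T @ Wt + lam * np.eye(m)]])
        sol = np.linalg.solve(A, np.r_[ones.T @ y, Wt.T @ y])
        gbv_oracle = W @ sol[1:]
        assert np.abs(fit.mu - sol[0]) < 1e-6
        assert np.abs(fit.gbv["gbv_total"].to_numpy() - gbv_oracle).max() < 1e-6

    def test_unrelated_target_gets_zero(self):
        ids = [f"s{i}" for i in range(6)]
        v = np.eye(6)
        grm = sb.grm.GRM(ids, v, "p", 10)
        y = np.array([1.0, -1.0, 0.5, 0.2, -0.7])
        vc = VarianceComponents({"p": 1.0}, 1.0, 0.0, True, 1)
        fit = gblup_predict(y, vc, [grm], ids[:5], [ids[5]])
        assert fit.gbv.loc["s5", "gbv_total"] == pytest.approx(0.0, abs=1e-12)

    def test_shrinkage_monotone_in_noise_ratio(self, pop800):
        g, _, _ = pop800
        ids = g.samples[:200]
        grm = compute_grm(g.subset(sample_ids=ids), "WGS", 0.01)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(200)
        norms = []
        for s2e in (0.1, 0.5, 2.0, 10.0):
            vc = VarianceComponents({"WGS": 1.0}, s2e, 0.0, True, 1)
            fit = gblup_predict(y, vc, [grm], ids)
            norms.append(np.linalg.norm(fit.gbv["gbv_total"]))
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_training_residuals_orthogonal_to_intercept(self, pop800):
        g, _, _ = pop800
        ids = g.samples[:200]
        grm = compute_grm(g.subset(sample_ids=ids), "WGS", 0.01)
        y = np.random.default_rng(4).standard_normal(200) + 3.0
        vc = VarianceComponents({"WGS": 0.5}, 0.5, 0.0, True, 1)
        fit = gblup_predict(y, vc, [grm], ids)
        resid = y - fit.mu - fit.gbv["gbv_total"].to_numpy()
        assert abs(resid.mean()) < 1e-8

    def test_blup_slope_near_one_on_held_out_animals(self, pop800):
        # regressing held-out phenotypes on their predicted GBV gives slope
        # ~1 when the model is well specified (the property behind the
        # bias metric)
        g, _, _ = pop800
        grm = compute_grm(g, "WGS", 0.01)
        slopes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, _ = simulate_trait(g, 0.35, seed)
            perm = rng.permutation(g.n_samples)
            tr = [g.samples[i] for i in perm[:600]]
            va = [g.samples[i] for i in perm[600:]]
            vc = greml(y[perm[:600]], [grm], sample_ids=tr)
            fit = gblup_predict(y[perm[:600]], vc, [grm], tr, va)
            gbv = fit.gbv.loc[va, "gbv_total"].to_numpy()
            yva = y[perm[600:]]
            slopes.append(np.cov(gbv, yva)[0, 1] / np.var(gbv))
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)


class TestHeritability:
    def test_equal_variances_gives_half(self):
        vc = VarianceComponents({"g": 1.0}, 1.0, 0.0, True, 1)
        assert heritability(vc)["total"] == 0.5

    def test_two_component_sum(self):
        vc = VarianceComponents({"g1": 0.116, "g2": 0.075}, 1.0 - 0.191, 0.0,
                                True, 1)
        h = heritability(vc)
        assert h["total"] == pytest.approx(h["g1"] + h["g2"])
        assert h["total"] == pytest.approx(0.191, abs=1e-12)

    def test_no_genetic_variance_gives_zero(self):
        vc = VarianceComponents({"g": 0.0}, 1.0, 0.0, True, 1)
        assert heritability(vc)["total"] == 0.0
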