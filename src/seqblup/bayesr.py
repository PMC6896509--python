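"""BayesR and BayesRC: four-component normal-mixture SNP effect models.

Each standardized SNP effect b_j is drawn from one of four zero-mean normal
classes with variances (0, 1e-4, 1e-3, 1e-2) x s2_g, where s2_g is the
additive genetic variance (resampled every iteration, so the class scales
are relative).  Gibbs sampling per iteration: each SNP's class is sampled
from its conditional posterior with the effect integrated out, then its
effect given the class; mixing proportions are Dirichlet-updated from the
class counts — per variant *category* under BayesRC, which is the only
difference between the two methods; s2_g and the residual variance have
scaled-inverse-chi-square conditionals.  The residual vector is maintained
incrementally so one iteration costs O(n m).

Genotypes enter centred and scaled to unit variance using training-set
means and SDs (targets are transformed with the training statistics), and
missing dosages become 0 after centring.  Production settings are 5 chains
of 40,000 iterations with 20,000 burn-in; tests and examples scale this
down and say so in their output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["MixtureSpec", "BayesRModel", "ChainResult", "StandardizedGenotypes",
           "standardize", "bayesr_fit", "bayesrc_fit", "bayes_predict",
           "bayes_heritability", "gelman_rubin"]

DEFAULT_SCALES = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class MixtureSpec:
    """Mixture-class variance scales, variant categories, Dirichlet prior."""

    variance_scales: tuple = DEFAULT_SCALES
    #: variant_id -> category label; empty = one category for all
    categories: dict = field(default_factory=dict)
    #: Dirichlet pseudo-counts per class (shared across categories)
    dirichlet_prior: tuple | None = None

    def __post_init__(self) -> None:
        sc = np.asarray(self.variance_scales, dtype=float)
        if (sc < 0).any():
            raise ValueError("variance scales must be non-negative")
        nonnull = sc[sc > 0]
        if not (np.diff(nonnull) > 0).all():
            raise ValueError("non-null variance scales must be strictly increasing")
        if self.dirichlet_prior is None:
            self.dirichlet_prior = tuple(1.0 for _ in sc)
        if len(self.dirichlet_prior) != sc.size:
            raise ValueError("Dirichlet prior length must match class count")

    def category_codes(self, variant_ids) -> tuple[np.ndarray, list[str]]:
        """Integer category per variant and the label list, '50k'-style."""
        if not self.categories:
            return np.zeros(len(variant_ids), dtype=np.int64), ["all"]
        labels = sorted(set(self.categories.values()))
        code = {lab: i for i, lab in enumerate(labels)}
        try:
            cats = np.array([code[self.categories[v]] for v in variant_ids])
        except KeyError as e:
            raise ValueError(f"variant {e.args[0]!r} has no category") from None
        return cats, labels


@dataclass
class StandardizedGenotypes:
    """Training-set standardization of a genotype matrix."""

    variant_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    _source: GenotypeMatrix

    def matrix(self, sample_ids) -> np.ndarray:
        """Standardized dosages for the given samples (missing -> 0)."""
        sub = self._source.subset(sample_ids=list(sample_ids))
        x = sub.dosage.astype(np.float64)
        miss = sub.dosage == MISSING
        x = (x - self.mean) / self.sd
        x[miss] = 0.0
        return x


def standardize(g: GenotypeMatrix, training_ids,
                variant_mask: np.ndarray | None = None) -> StandardizedGenotypes:
    """Centre/scale per variant using training samples only."""
    sub = g if variant_mask is None else g.subset(variant_mask=variant_mask)
    train = sub.subset(sample_ids=list(training_ids))
    x = train.dosage.astype(np.float64)
    obs = train.dosage != MISSING
    with np.errstate(invalid="ignore"):
        mean = np.where(obs, x, np.nan)
    mean = np.nanmean(mean, axis=0)
    centred = np.where(obs, x - mean, 0.0)
    sd = np.sqrt((centred ** 2).sum(axis=0) / np.maximum(obs.sum(axis=0), 1))
    bad = ~(sd > 0)
    if bad.any():
        vid = sub.variants.ids[bad][0]
        raise ValueError(f"variant {vid!r} has zero variance in the training set")
    return StandardizedGenotypes(sub.variants.ids, mean, sd, sub)


@njit(cache=True)
def _gibbs_kernel(y, X, cat, n_cat, gamma, alpha, n_iter, n_burnin, thin,
                  seed, nu0, s0_g, s0_e, fix_s2g, fix_s2e):
    np.random.seed(seed)
    n, m = X.shape
    n_cls = gamma.shape[0]
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    mu = np.mean(y)
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    e = y - mu
    s2e = s0_e if fix_s2e <= 0.0 else fix_s2e
    s2g = s0_g if fix_s2g <= 0.0 else fix_s2g
    pi = np.full((n_cat, n_cls), 1.0 / n_cls)

    n_kept = (n_iter - n_burnin) // thin
    s2g_s = np.empty(n_kept)
    s2e_s = np.empty(n_kept)
    h2_s = np.empty(n_kept)
    pi_s = np.empty((n_kept, n_cat, n_cls))
    beta_sum = np.zeros(m)
    cls_count = np.zeros((m, n_cls))
    kept = 0
    logw = np.empty(n_cls)

    for it in range(n_iter):
        # intercept
        mu_mean = mu + np.sum(e) / n
        mu_new = mu_mean + np.random.normal() * np.sqrt(s2e / n)
        for i in range(n):
            e[i] += mu - mu_new
        mu = mu_new

        counts = np.zeros((n_cat, n_cls))
        ssq_scaled = 0.0
        m_nz = 0
        for j in range(m):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            c_j = cat[j]
            maxw = -1e300
            for c in range(n_cls):
                g_c = gamma[c]
                if pi[c_j, c] <= 0.0:
                    logw[c] = -1e300
                elif g_c == 0.0:
                    logw[c] = np.log(pi[c_j, c])
                else:
                    v = g_c * s2g
                    C = xtx[j] + s2e / v
                    logw[c] = (np.log(pi[c_j, c])
                               - 0.5 * np.log(v * xtx[j] / s2e + 1.0)
                               + 0.5 * rhs * rhs / (s2e * C))
                if logw[c] > maxw:
                    maxw = logw[c]
            tot = 0.0
            for c in range(n_cls):
                logw[c] = np.exp(logw[c] - maxw)
                tot += logw[c]
            u = np.random.random() * tot
            acc = 0.0
            cls = n_cls - 1
            for c in range(n_cls):
                acc += logw[c]
                if u <= acc:
                    cls = c
                    break
            delta[j] = cls
            counts[c_j, cls] += 1.0
            if gamma[cls] == 0.0:
                beta[j] = 0.0
            else:
                v = gamma[cls] * s2g
                C = xtx[j] + s2e / v
                b_new = rhs / C + np.random.normal() * np.sqrt(s2e / C)
                beta[j] = b_new
                for i in range(n):
                    e[i] -= X[i, j] * b_new
                ssq_scaled += b_new * b_new / gamma[cls]
                m_nz += 1

        # mixing proportions per category
        for c_j in range(n_cat):
            tot = 0.0
            for c in range(n_cls):
                d = np.random.gamma(alpha[c] + counts[c_j, c], 1.0)
                pi[c_j, c] = d
                tot += d
            for c in range(n_cls):
                pi[c_j, c] /= tot

        # variance components (fixed values skip their update)
        if fix_s2g <= 0.0:
            s2g = (nu0 * s0_g + ssq_scaled) / np.random.chisquare(nu0 + m_nz)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        if fix_s2e <= 0.0:
            s2e = (nu0 * s0_e + sse) / np.random.chisquare(nu0 + n)
        if not np.isfinite(s2e) or not np.isfinite(s2g):
            return (beta_sum, cls_count, s2g_s, s2e_s, h2_s, pi_s, -1, it)

        if it >= n_burnin and (it - n_burnin) % thin == 0 and kept < n_kept:
            gmean = 0.0
            for i in range(n):
                gmean += y[i] - mu - e[i]
            gmean /= n
            vg = 0.0
            for i in range(n):
                d = (y[i] - mu - e[i]) - gmean
                vg += d * d
            vg /= n
            s2g_s[kept] = s2g
            s2e_s[kept] = s2e
            h2_s[kept] = vg / (vg + s2e) if vg + s2e > 0 else 0.0
            for c_j in range(n_cat):
                for c in range(n_cls):
                    pi_s[kept, c_j, c] = pi[c_j, c]
            beta_sum += beta
            for j in range(m):
                cls_count[j, delta[j]] += 1.0
            kept += 1
    return (beta_sum, cls_count, s2g_s, s2e_s, h2_s, pi_s, kept, n_iter)


@dataclass
class ChainResult:
    """Posterior summaries from one MCMC chain."""

    seed: int
    beta_mean: np.ndarray        # posterior-mean effects, standardized scale
    class_prob: np.ndarray       # (m, n_classes), rows sum to 1
    pi_mean: np.ndarray          # (n_cat, n_classes)
    s2g_samples: np.ndarray
    s2e_samples: np.ndarray
    h2_samples: np.ndarray
    pi_samples: np.ndarray

    @property
    def h2_mean(self) -> float:
        return float(self.h2_samples.mean())


@dataclass
class BayesRModel:
    """Multi-chain BayesR/BayesRC fit."""

    spec: MixtureSpec
    variant_ids: np.ndarray
    category_labels: list[str]
    chains: list[ChainResult]
    n_iter: int
    n_burnin: int

    @property
    def beta_mean(self) -> np.ndarray:
        """Across-chain posterior-mean standardized effects."""
        return np.mean([c.beta_mean for c in self.chains], axis=0)

    @property
    def class_prob(self) -> np.ndarray:
        return np.mean([c.class_prob for c in self.chains], axis=0)

    def summary(self) -> pd.DataFrame:
        rows = [{"chain": i, "seed": c.seed, "h2": c.h2_mean,
                 "s2g": float(c.s2g_samples.mean()),
                 "s2e": float(c.s2e_samples.mean())}
                for i, c in enumerate(self.chains)]
        return pd.DataFrame(rows)


def bayesr_fit(y: np.ndarray, Xstd: np.ndarray, variant_ids,
               spec: MixtureSpec | None = None, n_iter: int = 40_000,
               n_burnin: int = 20_000, n_chains: int = 5, seed: int = 0,
               thin: int = 10, nu0: float = 4.0, fix_s2g: float | None = None,
               fix_s2e: float | None = None) -> BayesRModel:
    """Fit the mixture model by Gibbs sampling, one or more chains.

    ``Xstd`` must be training-standardized genotypes (see :func:`standardize`);
    ``y`` the pre-adjusted phenotypes of the same samples.
    """
    if n_iter <= n_burnin:
        raise ValueError("n_iter must exceed n_burnin")
    spec = spec or MixtureSpec()
    y = np.asarray(y, dtype=float)
    Xstd = np.ascontiguousarray(Xstd, dtype=np.float64)
    if Xstd.shape[0] != y.size:
        raise ValueError("genotype rows do not match phenotype length")
    if Xstd.shape[1] != len(variant_ids):
        raise ValueError("genotype columns do not match variant ids")
    cats, labels = spec.category_codes(list(variant_ids))
    gamma = np.asarray(spec.variance_scales, dtype=float)
    alpha = np.asarray(spec.dirichlet_prior, dtype=float)
    vary = float(np.var(y))
    s0 = 0.5 * vary if vary > 0 else 0.5

    chains = []
    for c in range(n_chains):
        chain_seed = int((seed + 1000003 * c) % (2 ** 31 - 1))
        out = _gibbs_kernel(y, Xstd, cats.astype(np.int64), len(labels), gamma,
                            alpha, int(n_iter), int(n_burnin), int(thin),
                            chain_seed, float(nu0), s0, s0,
                            float(fix_s2g or 0.0), float(fix_s2e or 0.0))
        beta_sum, cls_count, s2g_s, s2e_s, h2_s, pi_s, kept, last_it = out
        if kept < 0:
            raise RuntimeError(f"divergent residual variance in chain {c} "
                               f"at iteration {last_it}")
        beta_mean = beta_sum / kept
        class_prob = cls_count / kept
        chains.append(ChainResult(
            seed=chain_seed, beta_mean=beta_mean, class_prob=class_prob,
            pi_mean=pi_s[:kept].mean(axis=0), s2g_samples=s2g_s[:kept],
            s2e_samples=s2e_s[:kept], h2_samples=h2_s[:kept],
            pi_samples=pi_s[:kept]))
    return BayesRModel(spec, np.asarray(variant_ids), labels, chains,
                       n_iter, n_burnin)


def bayesrc_fit(y: np.ndarray, Xstd: np.ndarray, variant_ids,
                categories: dict, variance_scales: tuple = DEFAULT_SCALES,
                **kwargs) -> BayesRModel:
    """BayesRC: identical sampler with independent mixing proportions per
    variant category (e.g. 'array' vs 'top')."""
    spec = MixtureSpec(variance_scales=variance_scales, categories=dict(categories))
    return bayesr_fit(y, Xstd, variant_ids, spec=spec, **kwargs)


def bayes_predict(model: BayesRModel, Xstd_target: np.ndarray) -> pd.DataFrame:
    """GBV per target sample: standardized genotypes times posterior-mean
    effects, per chain and chain-averaged."""
    out = {}
    for i, c in enumerate(model.chains):
        out[f"chain{i}"] = Xstd_target @ c.beta_mean
    df = pd.DataFrame(out)
    df["gbv_mean"] = df.mean(axis=1)
    return df


def bayes_heritability(model: BayesRModel) -> dict:
    """Posterior-mean h2 (variance explained by all SNPs) per chain and
    chain-averaged."""
    per_chain = [c.h2_mean for c in model.chains]
    return {"per_chain": per_chain, "mean": float(np.mean(per_chain))}


def gelman_rubin(samples_by_chain: list[np.ndarray]) -> float:
    """Potential scale reduction factor R-hat across chains."""
    chains = [np.asarray(s, dtype=float) for s in samples_by_chain]
    L = min(len(s) for s in chains)
    x = np.stack([s[-L:] for s in chains])
    m = x.shape[0]
    if m < 2 or L < 2:
        return 1.0
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = L * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (L - 1) / L * W + B / L
    return float(np.sqrt(var_hat / W))
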