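"""GREML variance estimation and GBLUP breeding-value prediction.

Model with k genomic components (k = 1 for a single panel, k = 2 for the
array + top-SNP decomposition):

    y = 1 mu + sum_j u_j + e,   u_j ~ N(0, G_j s2_j),   e ~ N(0, I s2_e).

Variance components are estimated by restricted maximum likelihood:
average-information (AI) updates after a few EM warm-up steps, with
estimates box-constrained at 1e-6 * var(y) (components are floored, never
dropped, so the component count is stable across traits).  With a single
genomic component the restricted likelihood is maximized exactly in the
eigenbasis of G, which is cheaper and used automatically.

Prediction is BLUP at the estimated ratios: with P the REML projection on
the training set, u_j = s2_j G_j[ . , train] P y for training and target
individuals alike, and the overall genomic breeding value is the sum over
components.  Heritability per component is s2_j divided by the phenotypic
variance sum(s2) + s2_e; the total is the sum over components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .grm import GRM
from .gwas import ConvergenceError, VarianceComponents

logger = logging.getLogger(__name__)

__all__ = ["GblupFit", "greml", "gblup_predict", "heritability"]

_FLOOR_FRAC = 1e-6  # variance floor as a fraction of var(y)


@dataclass
class GblupFit:
    """GREML variance components plus per-sample, per-component GBVs."""

    vc: VarianceComponents
    mu: float
    gbv: pd.DataFrame        # index sample_id; columns u1..uk, gbv_total
    training_ids: list[str]

    def __post_init__(self) -> None:
        comp = [c for c in self.gbv.columns if c.startswith("u")]
        total = self.gbv[comp].sum(axis=1)
        if not np.allclose(total, self.gbv["gbv_total"], atol=1e-10):
            raise ValueError("gbv_total is not the sum of components")


def _neg2ll_single(log_s2, d, yt, Xt):
    s2g, s2e = np.exp(log_s2)
    a = s2g * d + s2e
    Ainv_X = Xt / a[:, None]
    XtVX = Xt.T @ Ainv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    b = np.linalg.solve(XtVX, Ainv_X.T @ yt)
    Py = yt / a - Ainv_X @ b
    return float(np.sum(np.log(a)) + logdet_x + yt @ Py)


def _greml_single(y, G, max_iter, tol):
    vary = float(np.var(y))
    d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ np.ones((y.size, 1))
    lo, hi = np.log(_FLOOR_FRAC * vary), np.log(1e3 * vary)
    best = None
    for frac in (0.5, 0.1, 0.9):
        x0 = np.log(np.array([frac, 1 - frac]) * vary)
        r = optimize.minimize(_neg2ll_single, x0, args=(d, yt, Xt),
                              method="L-BFGS-B", bounds=[(lo, hi)] * 2,
                              options={"maxiter": max_iter, "ftol": 1e-13})
        if best is None or r.fun < best.fun - 1e-10:
            best = r
    if not np.isfinite(best.fun):
        raise ConvergenceError("single-component GREML failed")
    s2g, s2e = np.exp(best.x)
    return np.array([s2g]), float(s2e), -0.5 * best.fun, True, int(best.nit)


def _loglik_multi(theta, Gs, y, X):
    n = y.size
    V = theta[-1] * np.eye(n)
    for s2, G in zip(theta[:-1], Gs):
        V += s2 * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    Vinv_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Vinv_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    XtVX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    b = np.linalg.solve(XtVX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ b
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, Py, L, Vinv_X, XtVX

def _greml_ai(y, Gs, max_iter, tol, n_em=3):
    n = y.size
    k = len(Gs)
    vary = float(np.var(y))
    floor = _FLOOR_FRAC * vary
    X = np.ones((n, 1))
    theta = np.full(k + 1, vary / (k + 1))
    out = _loglik_multi(theta, Gs, y, X)
    if out is None:
        raise ConvergenceError("initial covariance not positive definite")
    ll, Py, L, Vinv_X, XtVX = out
    trace = [ll]

    def P_apply(B):
        Vinv_B = np.linalg.solve(L.T, np.linalg.solve(L, B))
        return Vinv_B - Vinv_X @ np.linalg.solve(XtVX, X.T @ Vinv_B)

    converged = False
    stalled = False
    it = 0
    for it in range(1, max_iter + 1):
        mats = list(Gs) + [np.eye(n)]
        yPGPy = np.array([float(Py @ (M @ Py)) for M in mats])
        # tr(P G) without forming P: tr(V^-1 G) minus the fixed-effect part
        trPG = np.empty(k + 1)
        for j, M in enumerate(mats):
            Vinv_M = np.linalg.solve(L.T, np.linalg.solve(L, M))
            corr = np.linalg.solve(XtVX, X.T @ (Vinv_M @ Vinv_X))
            trPG[j] = np.trace(Vinv_M) - float(np.trace(corr))
        score = -0.5 * (trPG - yPGPy)
        if it <= n_em:
            new = theta + (theta ** 2 / n) * (yPGPy - trPG)
        else:
            AI = np.empty((k + 1, k + 1))
            vecs = [M @ Py for M in mats]
            Pvecs = [P_apply(v) for v in vecs]
            for a in range(k + 1):
                for b in range(a, k + 1):
                    AI[a, b] = AI[b, a] = 0.5 * float(vecs[a] @ Pvecs[b])
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = score / np.maximum(np.diag(AI), 1e-12)
            new = theta + delta
        new = np.clip(new, floor, 1e3 * vary)
        # step-halving on likelihood decrease
        for _ in range(20):
            out = _loglik_multi(new, Gs, y, X)
            if out is not None and out[0] >= ll - 1e-10:
                break
            new = 0.5 * (new + theta)
        else:
            # no step improves the likelihood: converged to numerical precision
            stalled = True
            break
        new_ll = out[0]
        dll = new_ll - ll
        theta, (ll, Py, L, Vinv_X, XtVX) = new, out
        trace.append(ll)
        if abs(dll) < tol:
            converged = True
            break
    if not (converged or stalled):
        raise ConvergenceError("AI-REML did not converge", trace=trace)
    return theta[:-1], float(theta[-1]), float(ll), True, it


def greml(y: np.ndarray, grms: list[GRM], sample_ids=None, max_iter: int = 200,
          tol: float = 1e-8, jitter: float = 1e-6) -> VarianceComponents:
    """REML variance components for 1..3 genomic components plus residual."""
    if not 1 <= len(grms) <= 3:
        raise ValueError("greml supports 1 to 3 genomic components")
    y = np.asarray(y, dtype=float)
    if np.var(y) <= 0:
        raise ValueError("phenotype has zero variance")
    if sample_ids is None:
        sample_ids = list(grms[0].samples)
    Gs = [g.submatrix(sample_ids) + jitter * np.eye(len(sample_ids)) for g in grms]
    if len(Gs) == 1:
        s2, s2e, ll, conv, nit = _greml_single(y, Gs[0], max_iter, tol)
    else:
        s2, s2e, ll, conv, nit = _greml_ai(y, Gs, max_iter, tol)
    names = [g.panel_name for g in grms]
    if len(set(names)) != len(names):
        names = [f"{nm}_{j+1}" for j, nm in enumerate(names)]
    return VarianceComponents(dict(zip(names, map(float, s2))), s2e, ll, conv, nit)


def gblup_predict(y: np.ndarray, vc: VarianceComponents, grms: list[GRM],
                  training_ids, target_ids=()) -> GblupFit:
    """BLUP breeding values for training and target samples at fixed ratios."""
    y = np.asarray(y, dtype=float)
    training_ids = list(training_ids)
    target_ids = [t for t in target_ids if t not in set(training_ids)]
    n = len(training_ids)
    if y.size != n:
        raise ValueError("y length does not match training ids")
    s2 = list(vc.components.values())
    V = vc.sigma_e2 * np.eye(n)
    for s2j, g in zip(s2, grms):
        V += s2j * g.submatrix(training_ids)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    Vinv_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    ones = np.ones(n)
    Vinv_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
    mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    Py = Vinv_y - Vinv_1 * mu  # = V^-1 (y - 1 mu)

    all_ids = training_ids + target_ids
    comps = {}
    for j, (s2j, g) in enumerate(zip(s2, grms), start=1):
        cross = g.submatrix(all_ids, training_ids)
        comps[f"u{j}"] = s2j * (cross @ Py)
    gbv = pd.DataFrame(comps, index=pd.Index(all_ids, name="sample_id"))
    gbv["gbv_total"] = gbv.sum(axis=1)
    return GblupFit(vc, mu, gbv, training_ids)


def heritability(vc: VarianceComponents) -> dict:
    """Per-component and total h2 = genetic variance / phenotypic variance."""
    tot = vc.total
    if tot <= 0:
        return {name: 0.0 for name in vc.components} | {"total": 0.0}
    out = {name: s2 / tot for name, s2 in vc.components.items()}
    out["total"] = sum(out.values())
    return out
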