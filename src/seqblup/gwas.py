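"""Mixed-model association scan with population-structure control.

Model per variant i (dosage vector s_i, coded 0/1/2):

    y* = X b + s_i a_i + Q q + g + e,
    q ~ N(0, I sigma_q^2),  g ~ N(0, G sigma_g^2),  e ~ N(0, I sigma_e^2),

where X holds the intercept and any data-source factor, Q the pedigree
breed-proportion (and optional sub-breed) columns, and G a genomic
relationship matrix.  Variance components are estimated once by REML under
the null (no variant term) and then held fixed for every variant, which
turns each test into generalized least squares against V-hat — the standard
two-stage (EMMAX-style) approximation.  The per-variant statistic is a
two-sided Wald test with a Gaussian reference.

Computation: with G = U diag(d) U', all quantities are rotated by U' once;
V becomes diagonal plus the low-rank breed term, handled by the Woodbury
identity, so the null REML is a cheap 3-parameter optimization and the scan
is O(n^2) once plus O(n) per variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grm import GRM
from .io_formats import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "NullModelFit", "GwasResult",
           "fit_null_mixed_model", "gwas_scan"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, msg: str, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class VarianceComponents:
    """Named variance-component estimates from one (RE)ML fit."""

    components: dict[str, float]   # e.g. {"breed": s2_q, "genomic": s2_g}
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        for name, v in self.components.items():
            if v < 0:
                raise ValueError(f"negative variance for {name!r}")
        if self.sigma_e2 < 0:
            raise ValueError("negative residual variance")
        if self.converged and not np.isfinite(self.loglik):
            raise ValueError("converged fit with non-finite log-likelihood")

    @property
    def total(self) -> float:
        return sum(self.components.values()) + self.sigma_e2


@dataclass
class NullModelFit:
    """Null REML fit plus the spectral cache needed for fast per-variant GLS."""

    vc: VarianceComponents
    sample_ids: list[str]
    U: np.ndarray          # eigenvectors of G (n x n)
    d: np.ndarray          # eigenvalues of G
    y_rot: np.ndarray      # U' y*
    X_rot: np.ndarray      # U' X
    Q_rot: np.ndarray      # U' Q
    # Woodbury pieces at the REML optimum, filled by _finalize
    _a: np.ndarray = field(default=None, repr=False)
    _core_chol: np.ndarray = field(default=None, repr=False)
    _XtVinvX_inv: np.ndarray = field(default=None, repr=False)
    _VinvX: np.ndarray = field(default=None, repr=False)
    _Py: np.ndarray = field(default=None, repr=False)

    def vinv_apply(self, B: np.ndarray) -> np.ndarray:
        """V^-1 B for rotated B (columns are rotated n-vectors)."""
        AinvB = B / self._a[:, None]
        if self._core_chol is None:
            return AinvB
        Qt = self.Q_rot
        rhs = Qt.T @ AinvB
        z = np.linalg.solve(self._core_chol, rhs)
        z = np.linalg.solve(self._core_chol.T, z)
        return AinvB - (Qt / self._a[:, None]) @ z

    def p_apply(self, B: np.ndarray) -> np.ndarray:
        """P B = (V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1) B for rotated B."""
        VinvB = self.vinv_apply(B)
        return VinvB - self._VinvX @ (self._XtVinvX_inv @ (self.X_rot.T @ VinvB))


def _reml_neg_loglik(a: np.ndarray, s2_q: float, Qt: np.ndarray,
                     yt: np.ndarray, Xt: np.ndarray):
    """-2 * restricted log-likelihood (up to constants) and reusable pieces.

    a: diagonal of the rotated V without the breed term; the breed term is
    s2_q * Qt Qt' handled via Woodbury.
    """
    n, p = Xt.shape
    k = Qt.shape[1]
    use_q = s2_q > 0 and k > 0
    Ainv_y = yt / a
    Ainv_X = Xt / a[:, None]
    logdet_v = np.sum(np.log(a))
    if use_q:
        Ainv_Q = Qt / a[:, None]
        core = np.eye(k) / s2_q + Qt.T @ Ainv_Q
        L = np.linalg.cholesky(core)
        logdet_v += 2.0 * np.sum(np.log(np.diag(L))) + k * np.log(s2_q)

        def vinv(B, AinvB):
            z = np.linalg.solve(L, Qt.T @ AinvB)
            z = np.linalg.solve(L.T, z)
            return AinvB - Ainv_Q @ z
        Vinv_y = vinv(yt, Ainv_y)
        Vinv_X = vinv(Xt, Ainv_X)
    else:
        L = None
        Vinv_y, Vinv_X = Ainv_y, Ainv_X
    XtVX = Xt.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf, None
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ (Xt.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ (XtVX_inv @ (Xt.T @ Vinv_y))
    quad = float(yt @ Py)
    neg2ll = logdet_v + logdet_x + quad
    return neg2ll, (L, XtVX_inv, Vinv_X, Py, beta)


def fit_null_mixed_model(y: np.ndarray, X: np.ndarray, Q: np.ndarray,
                         grm: GRM, sample_ids=None, max_iter: int = 200,
                         tol: float = 1e-8, decomposition=None) -> NullModelFit:
    """REML fit of the null model y = Xb + Qq + g + e.

    ``y``, rows of ``X``/``Q`` and ``grm`` rows must align on the same
    samples (``sample_ids``, defaulting to the GRM's order).
    ``decomposition`` may pass a precomputed ``(eigenvalues, eigenvectors)``
    of the GRM block to amortize the spectral step over repeated fits on the
    same samples.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    n = y.size
    if sample_ids is None:
        sample_ids = list(grm.samples)
    G = grm.submatrix(sample_ids)
    if n < X.shape[1] + 2:
        raise ValueError("too few samples for the fixed design")
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular fixed-effect design (aliased columns)")

    if decomposition is None:
        d, U = np.linalg.eigh(G)
    else:
        d, U = decomposition
    d = np.clip(d, 0.0, None)
    yt, Xt, Qt = U.T @ y, U.T @ X, U.T @ Q

    def objective(theta):
        s2_q, s2_g, s2_e = np.exp(theta)
        a = s2_g * d + s2_e
        val, _ = _reml_neg_loglik(a, s2_q, Qt, yt, Xt)
        return val if np.isfinite(val) else 1e10

    x0 = np.log(np.array([0.05, 0.45, 0.5]) * vary)
    lo, hi = np.log(1e-8 * vary), np.log(1e3 * vary)
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            bounds=[(lo, hi)] * 3,
                            options={"maxiter": max_iter, "ftol": 1e-12})
    # multi-start guard against the boundary basin
    best = res
    for alt in ([0.3, 0.05, 0.65], [0.01, 0.8, 0.19]):
        r = optimize.minimize(objective, np.log(np.array(alt) * vary),
                              method="L-BFGS-B", bounds=[(lo, hi)] * 3,
                              options={"maxiter": max_iter, "ftol": 1e-12})
        if r.fun < best.fun - 1e-10:
            best = r
    if not np.isfinite(best.fun):
        raise ConvergenceError("null REML did not reach a finite optimum",
                               trace=[best.message])
    success = bool(best.success)
    best_x, best_fun = best.x, best.fun
    if not success:
        # L-BFGS line searches can abort at an effectively stationary point;
        # confirm with a derivative-free polish
        polish = optimize.minimize(objective, best_x, method="Nelder-Mead",
                                   options={"maxiter": 400, "xatol": 1e-10,
                                            "fatol": 1e-12})
        if polish.fun <= best_fun + 1e-9:
            improvement = best_fun - polish.fun
            best_x, best_fun = polish.x, polish.fun
            success = improvement < 1e-6 or bool(polish.success)
    best = optimize.OptimizeResult(x=best_x, fun=best_fun, success=success,
                                   nit=int(best.nit))
    s2_q, s2_g, s2_e = np.exp(best.x)
    a = s2_g * d + s2_e
    neg2ll, pieces = _reml_neg_loglik(a, s2_q, Qt, yt, Xt)
    L, XtVX_inv, Vinv_X, Py, _beta = pieces
    vc = VarianceComponents({"breed": float(s2_q), "genomic": float(s2_g)},
                            float(s2_e), -0.5 * neg2ll, bool(best.success),
                            int(best.nit))
    fit = NullModelFit(vc, list(sample_ids), U, d, yt, Xt, Qt)
    fit._a = a
    fit._core_chol = None if L is None else L * 1.0
    # _reml_neg_loglik's L is for core with 1/s2_q; vinv_apply rebuilds from it
    if L is not None:
        fit._core_chol = np.linalg.cholesky(np.eye(Qt.shape[1]) / s2_q
                                            + Qt.T @ (Qt / a[:, None]))
    fit._XtVinvX_inv = XtVX_inv
    fit._VinvX = Vinv_X
    fit._Py = Py
    return fit


@dataclass
class GwasResult:
    """Per-variant effect estimates and Wald p-values, in variant order."""

    table: pd.DataFrame  # variant_id chrom pos_bp beta se p_value maf n_used reason

    def significant(self, p_thresh: float) -> pd.DataFrame:
        t = self.table
        return t[t["p_value"] < p_thresh]


def gwas_scan(g: GenotypeMatrix, null_fit: NullModelFit, maf_min: float = 0.005,
              chunk: int = 2048) -> GwasResult:
    """Two-stage GLS scan of every variant against the null-fit covariance.

    Variants with discovery MAF below ``maf_min`` or no genotypic variance
    after projection get a missing p-value with a reason code.
    """
    if not null_fit.vc.converged:
        raise ValueError("null model fit did not converge")
    sub = g.subset(sample_ids=null_fit.sample_ids)
    n, m = sub.n_samples, sub.n_variants
    p_hat = sub.allele_freq()
    maf = np.minimum(p_hat, 1 - p_hat)
    dosage = sub.dosage_float(impute_mean=True)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    reason = np.array([""] * m, dtype=object)
    n_used = (sub.dosage != MISSING).sum(axis=0)

    testable = (maf >= maf_min) & (maf > 0)
    reason[~testable & (maf == 0)] = "monomorphic"
    reason[~testable & (maf > 0)] = "low_maf"

    idx = np.flatnonzero(testable)
    U, ssq_tol = null_fit.U, 1e-12
    for start in range(0, idx.size, chunk):
        cols = idx[start:start + chunk]
        S = U.T @ dosage[:, cols]
        PS = null_fit.p_apply(S)
        sPs = np.einsum("ij,ij->j", S, PS)
        sPy = PS.T @ null_fit.y_rot
        ok = sPs > ssq_tol * n
        b = np.where(ok, sPy / np.where(ok, sPs, 1.0), np.nan)
        s = np.where(ok, 1.0 / np.sqrt(np.where(ok, sPs, 1.0)), np.nan)
        beta[cols] = b
        se[cols] = s
        z = b / s
        pval[cols] = 2.0 * stats.norm.sf(np.abs(z))
        bad = cols[~ok]
        reason[bad] = "monomorphic"
        beta[bad] = np.nan
        se[bad] = np.nan
        pval[bad] = np.nan

    # p in (0,1]: clamp exact zeros from extreme z
    tiny = np.finfo(float).tiny
    pval = np.where(np.isfinite(pval), np.clip(pval, tiny, 1.0), np.nan)

    vdf = sub.variants.df
    table = pd.DataFrame({
        "variant_id": vdf["variant_id"].to_numpy(),
        "chrom": vdf["chrom"].to_numpy(),
        "pos_bp": vdf["pos_bp"].to_numpy(),
        "beta": beta, "se": se, "p_value": pval,
        "maf_discovery": maf, "n_used": n_used,
        "reason": reason,
    })
    return GwasResult(table)


def design_matrices(samples: SampleTable, ids=None,
                    subgroup_columns: bool = True):
    """Build (y*, X, Q) for the scan: X = intercept + data-source factor,
    Q = breed proportions (plus sub-breed columns when present)."""
    df = samples.df
    if ids is not None:
        df = df.set_index("sample_id").loc[list(ids)].reset_index()
    y = df["corrected_phenotype"].to_numpy(dtype=float)
    if np.isnan(y).any():
        y = df["phenotype"].to_numpy(dtype=float)
    src = pd.get_dummies(df["data_source"].astype(str), drop_first=True)
    X = np.column_stack([np.ones(len(df))] + [src[c].to_numpy(float) for c in src])
    cols = [c for c in df.columns if c.startswith("breed_")]
    Q = df[cols].to_numpy(dtype=float)
    if subgroup_columns and "subgroup" in df.columns:
        subs = df["subgroup"].astype(str)
        have = sorted(s for s in subs.unique() if s not in (".", "nan", "None"))
        if have:
            sub_cols = np.column_stack(
                [((subs == s) & (df[cols[0]] == 1.0)).to_numpy(float) for s in have])
            Q = np.column_stack([Q, sub_cols])
    return y, X, Q
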