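"""Validation metrics: heritability-scaled accuracy and regression-slope bias.

Accuracy = Pearson r(GBV, corrected phenotype) / sqrt(h2_ref), where h2_ref
is always the single-GRM GREML heritability from the 50k-style array panel
on the training set — the same denominator for every method, so methods
differ only in the correlation.  Bias = OLS slope of the corrected phenotype
on the GBV (1 = unbiased; < 1 means predictions are over-dispersed).
Bayesian fits are scored per MCMC chain and the metrics averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SCENARIOS", "accuracy", "bias", "chain_average", "method_grid"]

#: the standard prediction-scenario grid: six GBLUP variants, four BayesR
#: panels and BayesRC on the joint panel
SCENARIOS = (
    "GBLUP-top", "GBLUP-50k", "GBLUP-50k+top-1GRM", "2GBLUP",
    "GBLUP-HD", "GBLUP-WGS",
    "BayesR-top", "BayesR-50k", "BayesR-50k+top", "BayesR-HD",
    "BayesRC",
)

BENCHMARK = "GBLUP-50k"


def accuracy(gbv, y_star, h2_ref: float) -> float:
    """Pearson correlation of GBV with corrected phenotype, scaled by
    1/sqrt(h2_ref).  Pairs with a missing value in either vector are dropped."""
    if not (0.0 < h2_ref <= 1.0):
        raise ValueError("h2_ref must be in (0, 1]")
    gbv = np.asarray(gbv, dtype=float)
    y = np.asarray(y_star, dtype=float)
    ok = np.isfinite(gbv) & np.isfinite(y)
    gbv, y = gbv[ok], y[ok]
    if gbv.size < 10:
        raise ValueError(f"need >= 10 complete pairs, have {gbv.size}")
    if gbv.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in GBV or phenotype")
    r = float(np.corrcoef(gbv, y)[0, 1])
    return r / np.sqrt(h2_ref)


def bias(gbv, y_star) -> float:
    """OLS slope of corrected phenotype on GBV."""
    gbv = np.asarray(gbv, dtype=float)
    y = np.asarray(y_star, dtype=float)
    ok = np.isfinite(gbv) & np.isfinite(y)
    gbv, y = gbv[ok], y[ok]
    if gbv.size < 2 or np.var(gbv) == 0:
        raise ValueError("GBV variance is zero; slope undefined")
    return float(np.cov(gbv, y, ddof=0)[0, 1] / np.var(gbv))


def chain_average(per_chain: dict | pd.DataFrame) -> dict:
    """Arithmetic mean of each metric across MCMC chains."""
    df = pd.DataFrame(per_chain)
    if df.empty:
        raise ValueError("no chains to average")
    return {col: float(df[col].mean()) for col in df.columns}


@dataclass
class _Row:
    method: str
    group: str
    n: int
    accuracy: float
    bias: float
    flagged: str = ""


def method_grid(gbv_by_method: dict, y_star_by_group: dict, h2_ref: float,
                scenarios=SCENARIOS) -> pd.DataFrame:
    """Score every prediction scenario in every validation group.

    ``gbv_by_method``: method label -> per-sample GBV, either a Series
    (indexed by sample id) for one prediction or a DataFrame whose ``chain*``
    columns are per-MCMC-chain GBVs (metrics are then chain-averaged).
    ``y_star_by_group``: group label -> Series of corrected phenotypes
    indexed by validation sample id.  Scenarios without a supplied fit are
    emitted flagged, never dropped.  Deltas are reported against
    ``GBLUP-50k`` when present.
    """
    rows: list[_Row] = []
    for method in scenarios:
        fit = gbv_by_method.get(method)
        for group, y in y_star_by_group.items():
            n = int(y.notna().sum())
            if fit is None:
                rows.append(_Row(method, group, n, np.nan, np.nan, "missing_fit"))
                continue
            if n < 30:
                warnings.warn(f"{method}/{group}: only {n} validation animals")
            if isinstance(fit, pd.DataFrame):
                cols = [c for c in fit.columns if c.startswith("chain")]
                accs, slopes = [], []
                for c in cols:
                    g = fit[c].reindex(y.index)
                    accs.append(accuracy(g, y, h2_ref))
                    slopes.append(bias(g, y))
                avg = chain_average({"accuracy": accs, "bias": slopes})
                rows.append(_Row(method, group, n, avg["accuracy"], avg["bias"]))
            else:
                g = fit.reindex(y.index)
                rows.append(_Row(method, group, n,
                                 accuracy(g, y, h2_ref), bias(g, y)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["h2_ref"] = h2_ref
    bench = out[out["method"] == BENCHMARK].set_index("group")["accuracy"]
    out["delta_vs_benchmark"] = out.apply(
        lambda r: r["accuracy"] - bench.get(r["group"], np.nan), axis=1)
    return out
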