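"""Genomic relationship matrices (VanRaden method 1) and relationship queries.

G = W W' / (2 * sum_j p_j (1 - p_j)) where W is the dosage matrix centred by
twice the observed allele frequency.  Missing dosages are mean-imputed (to
2p) before centring, so they contribute nothing to relationships.  Allele
frequencies are always computed in the sample set the matrix is built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, write_grm_bin

logger = logging.getLogger(__name__)

__all__ = ["GRM", "compute_grm", "max_cross_relationship"]


@dataclass
class GRM:
    """Symmetric realized-relationship matrix over a named variant panel."""

    samples: list[str]
    values: np.ndarray
    panel_name: str
    n_variants_used: int
    n_variants_excluded: int = 0
    #: VanRaden scaling constant 2*sum p(1-p) over the variants used; maps
    #: per-allele effect variance tau^2 to the genetic variance d*tau^2
    denominator: float = float("nan")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.samples), len(self.samples)):
            raise ValueError("GRM shape does not match sample count")
        if not np.isfinite(v).all():
            raise ValueError("GRM has non-finite entries")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("GRM not symmetric")
        if self.n_variants_used < 1:
            raise ValueError("GRM built from zero variants")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.samples)

    def index_of(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in GRM {self.panel_name!r}") from None

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        ri = self.index_of(row_ids)
        ci = ri if col_ids is None else self.index_of(col_ids)
        return self.values[np.ix_(ri, ci)]

    def summary(self) -> dict:
        """Mean/SD of diagonal and off-diagonal entries (panel comparability check)."""
        d = np.diag(self.values)
        off = self.values[np.triu_indices(self.n, k=1)]
        return {
            "panel": self.panel_name, "n": self.n, "m": self.n_variants_used,
            "diag_mean": float(d.mean()), "diag_sd": float(d.std()),
            "offdiag_mean": float(off.mean()) if off.size else 0.0,
            "offdiag_sd": float(off.std()) if off.size else 0.0,
        }

    def to_gcta(self, path_prefix) -> None:
        write_grm_bin(self.values, self.samples, path_prefix, self.n_variants_used)


def compute_grm(g: GenotypeMatrix, panel: str = "WGS", maf_min: float = 0.0,
                variant_mask: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 GRM from the variants of a named panel.

    ``variant_mask`` overrides the panel lookup (for custom sets such as the
    selected top SNPs).  Variants with MAF below ``maf_min`` or with zero
    variance are excluded and counted.
    """
    if variant_mask is None:
        mask = g.variants.panel_mask(panel)
    else:
        mask = np.asarray(variant_mask, dtype=bool).copy()
    m0 = int(mask.sum())
    if m0 == 0:
        raise ValueError(f"panel {panel!r} has no variants")

    sub = g.dosage[:, mask].astype(np.float64)
    miss = sub == MISSING
    obs = ~miss
    counts = np.where(obs, sub, 0.0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    p = counts / (2.0 * np.maximum(n_obs, 1))
    mean_obs = counts / np.maximum(n_obs, 1)
    sq = np.where(obs, sub ** 2, 0.0).sum(axis=0) / np.maximum(n_obs, 1)
    var_obs = sq - mean_obs ** 2
    keep = ((np.minimum(p, 1 - p) >= maf_min) & (p > 0) & (p < 1)
            & (n_obs > 0) & (var_obs > 0))
    n_excluded = m0 - int(keep.sum())
    if not keep.any():
        raise ValueError(f"no variants of panel {panel!r} pass maf_min={maf_min}")
    if n_excluded:
        logger.info("GRM %s: excluded %d/%d variants (MAF < %g or monomorphic)",
                    panel, n_excluded, m0, maf_min)

    w = sub[:, keep]
    pk = p[keep]
    w[miss[:, keep]] = 0.0           # will be set to 2p by centring offset
    w = np.where(obs[:, keep], w - 2.0 * pk, 0.0)
    denom = 2.0 * np.sum(pk * (1.0 - pk))
    values = (w @ w.T) / denom
    values = 0.5 * (values + values.T)
    return GRM(list(g.samples), values, panel, int(keep.sum()), n_excluded,
               float(denom))


def max_cross_relationship(grm: GRM, set_a, set_b) -> tuple[float, tuple[str, str]]:
    """Exact maximum relationship over the set_a x set_b block of the GRM."""
    a = list(set_a)
    b = list(set_b)
    if set(a) & set(b):
        raise ValueError("sets must be disjoint")
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    block = grm.submatrix(a, b)
    i, j = np.unravel_index(np.argmax(block), block.shape)
    return float(block[i, j]), (a[i], b[j])
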