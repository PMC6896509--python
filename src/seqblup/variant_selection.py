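"""Selection of 'top SNPs' from an association scan.

The recipe: per chromosome, 100-kb windows sliding by 50 kb from position 1;
in each window keep the single most significant variant if its p-value beats
1e-3; collapse duplicates from overlapping windows; greedily drop the weaker
of any retained pair with r^2 > 0.95 on the same chromosome; drop candidates
whose minor allele frequency in the prediction *training* set falls below
0.005; and finally, when the top set is fitted alongside the array panel as
a separate component, move any top SNP that is also on the array out of the
array panel (the array keeps them when it is used alone).

Every removal is recorded with a reason so that
|candidates| = |retained| + |removals| always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GwasResult
from .io_formats import GenotypeMatrix, VariantTable

__all__ = ["TopSnpSet", "select_window_tops", "ld_prune", "maf_filter",
           "harmonize_with_array", "select_top_snps"]


@dataclass
class TopSnpSet:
    """Ordered retained top SNPs plus the audited removals."""

    variant_ids: list[str]
    provenance: dict[str, dict]                 # id -> window_start/end, p_value
    removed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate ids in top-SNP set")

    def __len__(self) -> int:
        return len(self.variant_ids)


def select_window_tops(gwas: GwasResult, variants: VariantTable,
                       window_bp: int = 100_000, step_bp: int = 50_000,
                       p_thresh: float = 1e-3) -> TopSnpSet:
    """Most significant variant per sliding window, below the threshold.

    Windows are [1, window_bp], [step_bp+1, step_bp+window_bp], ... (1-based
    inclusive) per chromosome, truncated at the last variant.  A variant
    winning several overlapping windows is kept once; the extra wins are
    audited as DUPLICATE_WINDOW.  Ties on p break to the smaller position,
    then the lexicographically smaller id.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    t = gwas.table.merge(variants.df[["variant_id"]], on="variant_id")
    t = t[t["p_value"].notna() & (t["p_value"] < p_thresh)]
    retained: list[str] = []
    seen: set[str] = set()
    prov: dict[str, dict] = {}
    removed: list[tuple[str, str]] = []
    for _chrom, sub in t.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if pos.size == 0:
            continue
        sub = sub.sort_values(["p_value", "pos_bp", "variant_id"])
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            inw = sub[(sub["pos_bp"] >= start) & (sub["pos_bp"] <= end)]
            if len(inw):
                best = inw.iloc[0]
                vid = best["variant_id"]
                if vid in seen:
                    removed.append((vid, "DUPLICATE_WINDOW"))
                else:
                    seen.add(vid)
                    retained.append(vid)
                    prov[vid] = {"window_start": start, "window_end": end,
                                 "p_value": float(best["p_value"])}
            start += step_bp
    return TopSnpSet(retained, prov, removed)


def _r2_matrix(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (zero-variance -> 0)."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    r = (xc / sd_safe).T @ (xc / sd_safe) / x.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    return r ** 2


def ld_prune(candidates: TopSnpSet, g: GenotypeMatrix,
             r2_max: float = 0.95) -> TopSnpSet:
    """Greedy prune in ascending p order: drop a candidate whose r^2 with an
    already-retained candidate on the same chromosome exceeds ``r2_max``."""
    ids = candidates.variant_ids
    vdf = g.variants.df.set_index("variant_id")
    missing = [v for v in ids if v not in vdf.index]
    if missing:
        raise KeyError(f"candidate {missing[0]!r} not genotyped")
    order = sorted(ids, key=lambda v: (candidates.provenance[v]["p_value"],
                                       vdf.loc[v, "pos_bp"], v))
    col_of = {v: i for i, v in enumerate(g.variants.ids)}
    x = g.dosage_float(impute_mean=True)
    kept: list[str] = []
    removed = list(candidates.removed)
    kept_by_chrom: dict[str, list[str]] = {}
    for v in order:
        chrom = vdf.loc[v, "chrom"]
        rivals = kept_by_chrom.get(chrom, [])
        drop = False
        if rivals:
            xv = x[:, col_of[v]]
            xr = x[:, [col_of[r] for r in rivals]]
            r2 = _r2_matrix(np.column_stack([xv, xr]))[0, 1:]
            drop = bool((r2 > r2_max).any())
        if drop:
            removed.append((v, "LD_PRUNED"))
        else:
            kept.append(v)
            kept_by_chrom.setdefault(chrom, []).append(v)
    kept_in_order = [v for v in ids if v in set(kept)]
    prov = {v: candidates.provenance[v] for v in kept_in_order}
    return TopSnpSet(kept_in_order, prov, removed)


def maf_filter(candidates: TopSnpSet, g_training: GenotypeMatrix,
               maf_min: float = 0.005) -> TopSnpSet:
    """Drop candidates with training-set MAF strictly below ``maf_min``
    (a variant at exactly the threshold is kept)."""
    maf = dict(zip(g_training.variants.ids, g_training.maf()))
    kept, removed = [], list(candidates.removed)
    for v in candidates.variant_ids:
        if v not in maf:
            raise KeyError(f"candidate {v!r} not genotyped in the training set")
        if maf[v] < maf_min:
            removed.append((v, "LOW_MAF"))
        else:
            kept.append(v)
    prov = {v: candidates.provenance[v] for v in kept}
    return TopSnpSet(kept, prov, removed)


def harmonize_with_array(top: TopSnpSet, array_panel) -> tuple[TopSnpSet, set]:
    """Resolve overlap for joint models: overlapping ids stay top SNPs and
    leave the array panel.  (Use the original panel when the array is fitted
    alone.)  Returns (top, reduced array panel)."""
    array_panel = set(array_panel)
    overlap = array_panel & set(top.variant_ids)
    return top, array_panel - overlap


def select_top_snps(gwas: GwasResult, g_discovery: GenotypeMatrix,
                    g_training: GenotypeMatrix, window_bp: int = 100_000,
                    step_bp: int = 50_000, p_thresh: float = 1e-3,
                    r2_max: float = 0.95, maf_min: float = 0.005) -> TopSnpSet:
    """Full selection pipeline: window tops -> LD prune -> MAF filter.

    r^2 for pruning is computed in the discovery genotypes; MAF in the
    training genotypes.  Deterministic given its inputs.
    """
    tops = select_window_tops(gwas, g_discovery.variants, window_bp, step_bp, p_thresh)
    tops = ld_prune(tops, g_discovery, r2_max)
    return maf_filter(tops, g_training, maf_min)
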