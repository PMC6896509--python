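"""Discovery / training / validation partitioning and phenotype pre-correction.

The split mirrors a relationship-controlled validation design: about 30% of
phenotyped animals (breed-stratified, seeded-random) form the GWAS discovery
set; validation animals are drawn only from named breed groups (e.g. one
purebred group and the F1 cross) and are excluded — moved to UNUSED, never
into training — whenever

* their recorded sire is in the training set,
* a paternal half-sib (same recorded sire) is in the training set, or
* their maximum genomic relationship to any training animal reaches the
  threshold (0.25 for meat-type traits, 0.125 for wool-type traits in the
  motivating design).

Every exclusion is recorded in the audit trail.  Pre-correction removes
fixed-effect and breed-group (genetic-group) estimates from the phenotype
using the same mixed model as the association scan with no variant term;
the polygenic BLUP itself is *not* removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GRM
from .gwas import fit_null_mixed_model
from .io_formats import SampleTable

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "partition", "precorrect", "check_split"]


@dataclass
class SplitSpec:
    """Role assignment per sample plus the audit of constrained exclusions."""

    roles: dict[str, str]           # sample_id -> role
    grm_threshold: float
    validation_groups: list[str]
    audit: list[dict] = field(default_factory=list)

    def ids(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.roles),
                             "role": list(self.roles.values())})


def partition(samples: SampleTable, grm: GRM, discovery_frac: float = 0.30,
              grm_threshold: float = 0.25, validation_groups=("purebred_0", "F1"),
              validation_frac: float = 0.5, seed: int = 0) -> SplitSpec:
    """Three-way split with sire, half-sib and relationship constraints.

    ``validation_groups`` entries are matched against the ``group`` column of
    the sample table when present, else against breed composition
    (``purebred_<i>`` = breed i proportion 1; ``F1`` = maximal proportion
    0.5).  ``validation_frac`` of each group's non-discovery members are
    proposed for validation before constraints are applied.
    """
    df = samples.df
    phenotyped = df[df["phenotype"].notna()].copy()
    if phenotyped.empty:
        raise ValueError("no phenotyped samples to partition")
    rng = np.random.default_rng(seed)

    breed_cols = [c for c in df.columns if c.startswith("breed_")]

    def group_members(gname: str) -> pd.DataFrame:
        if "group" in phenotyped.columns and (phenotyped["group"] == gname).any():
            return phenotyped[phenotyped["group"] == gname]
        if gname.startswith("purebred_"):
            b = f"breed_{gname.split('_', 1)[1]}"
            return phenotyped[phenotyped[b] == 1.0]
        if gname == "F1":
            props = phenotyped[breed_cols].to_numpy(float)
            return phenotyped[np.isclose(props.max(axis=1), 0.5)]
        raise ValueError(f"unknown validation group {gname!r}")

    # breed-stratified discovery draw
    strata = phenotyped[breed_cols].round(3).astype(str).agg("|".join, axis=1)
    discovery: list[str] = []
    for _, sub in phenotyped.groupby(strata):
        ids = sub["sample_id"].to_numpy()
        k = int(round(discovery_frac * ids.size))
        discovery.extend(rng.choice(ids, size=k, replace=False))
    discovery_set = set(discovery)

    sire_of = dict(zip(df["sample_id"], df["sire_id"]))
    audit: list[dict] = []

    # validation candidates are drawn whole paternal half-sib families at a
    # time, so a family is never split between training and validation: every
    # non-discovery member of a selected sire family leaves the training pool
    # (members outside the validation groups become UNUSED, audited).
    rest = phenotyped[~phenotyped["sample_id"].isin(discovery_set)]
    candidates: list[str] = []
    reserved_sires: set = set()
    for gname in validation_groups:
        mem = group_members(gname)
        mem = mem[~mem["sample_id"].isin(discovery_set)]
        target = int(round(validation_frac * len(mem)))
        fam_keys = mem["sire_id"].fillna("__none__") + "//" + mem["sample_id"].where(
            mem["sire_id"].isna(), "")
        families = [grp["sample_id"].tolist()
                    for _, grp in mem.groupby(fam_keys, sort=True)]
        order = rng.permutation(len(families))
        n_taken = 0
        for fi in order:
            if n_taken >= target:
                break
            fam = families[fi]
            candidates.extend(fam)
            n_taken += len(fam)
            sire = sire_of.get(fam[0])
            if sire:
                reserved_sires.add(sire)
    candidate_set = set(candidates)

    roles = {s: "UNUSED" for s in df["sample_id"]}
    for s in discovery_set:
        roles[s] = "DISCOVERY"
    training: list[str] = []
    for s in rest["sample_id"]:
        if s in candidate_set:
            continue
        sire = sire_of.get(s)
        if sire and sire in reserved_sires:
            audit.append({"sample_id": s, "reason": "half_sib_family_reserved",
                          "other": sire, "value": np.nan})
            continue
        training.append(s)
        roles[s] = "TRAINING"
    training_set = set(training)
    training_sires = {sire_of[s] for s in training if sire_of.get(s)}

    validation: list[str] = []
    for s in candidates:
        sire = sire_of.get(s)
        if sire and sire in training_set:
            audit.append({"sample_id": s, "reason": "sire_in_training",
                          "other": sire, "value": np.nan})
            continue
        if sire and sire in training_sires:
            audit.append({"sample_id": s, "reason": "half_sib_in_training",
                          "other": sire, "value": np.nan})
            continue
        rel = grm.submatrix([s], training)[0]
        j = int(np.argmax(rel))
        if rel[j] >= grm_threshold:
            audit.append({"sample_id": s, "reason": "relationship",
                          "other": training[j], "value": float(rel[j])})
            continue
        validation.append(s)
    for s in validation:
        roles[s] = "VALIDATION"

    if not validation:
        counts = pd.Series([a["reason"] for a in audit]).value_counts().to_dict()
        raise ValueError(f"validation set empty after constraints: {counts}")
    spec = SplitSpec(roles, grm_threshold, list(validation_groups), audit)
    check_split(spec, samples, grm)
    logger.info("partition: %d discovery, %d training, %d validation, %d excluded",
                len(discovery_set), len(training), len(validation), len(audit))
    return spec


def check_split(spec: SplitSpec, samples: SampleTable, grm: GRM) -> None:
    """Brute-force verification of the split invariants; raises on violation."""
    df = samples.df
    sire_of = dict(zip(df["sample_id"], df["sire_id"]))
    training = set(spec.ids("TRAINING"))
    validation = spec.ids("VALIDATION")
    phenotyped = set(df.loc[df["phenotype"].notna(), "sample_id"])
    for s, r in spec.roles.items():
        if r != "UNUSED" and s not in phenotyped:
            raise AssertionError(f"{s} assigned {r} without a phenotype")
    training_sires = {sire_of[s] for s in training if sire_of.get(s)}
    for v in validation:
        sire = sire_of.get(v)
        if sire and sire in training:
            raise AssertionError(f"sire of validation animal {v} is in training")
        if sire and sire in training_sires:
            raise AssertionError(f"half-sib family of {v} spans training/validation")
    if training and validation:
        block = grm.submatrix(validation, sorted(training))
        if block.max() >= spec.grm_threshold:
            i, j = np.unravel_index(np.argmax(block), block.shape)
            raise AssertionError(
                f"validation {validation[i]} related {block[i, j]:.3f} to training")


def precorrect(samples: SampleTable, grm: GRM, fixed_columns=("data_source",),
               sample_ids=None) -> SampleTable:
    """Remove fixed-effect and genetic-group estimates from the phenotype.

    Fits y = Xb + Qq + g + e by REML (X = intercept + the named factor
    columns, Q = breed proportions, g polygenic against ``grm``) and stores
    y - X b-hat - Q q-hat as ``corrected_phenotype``.  The polygenic term is
    left in the phenotype.
    """
    df = samples.df
    sub = df[df["phenotype"].notna()]
    if sample_ids is not None:
        sub = sub[sub["sample_id"].isin(set(sample_ids))]
    ids = sub["sample_id"].tolist()
    y = sub["phenotype"].to_numpy(float)

    X_cols = [np.ones(len(sub))]
    for col in fixed_columns:
        if col not in sub.columns:
            continue
        dummies = pd.get_dummies(sub[col].astype(str), drop_first=True)
        X_cols.extend(dummies[c].to_numpy(float) for c in dummies)
    X = np.column_stack(X_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular fixed-effect design: aliased factor levels "
                         f"in {list(fixed_columns)}")
    breed_cols = [c for c in sub.columns if c.startswith("breed_")]
    Q = sub[breed_cols].to_numpy(float)

    fit = fit_null_mixed_model(y, X, Q, grm, sample_ids=ids)
    yt = fit.y_rot
    # GLS fixed effects and breed-group BLUP at the REML optimum
    Vinv_y = fit.vinv_apply(yt[:, None])[:, 0]
    b_hat = fit._XtVinvX_inv @ (fit.X_rot.T @ Vinv_y)
    resid_rot = yt - fit.X_rot @ b_hat
    q_hat = fit.vc.components["breed"] * (fit.Q_rot.T @ fit.vinv_apply(resid_rot[:, None])[:, 0])
    corrected = y - X @ b_hat - Q @ q_hat

    out = df.copy()
    out.loc[out["sample_id"].isin(set(ids)), "corrected_phenotype"] = pd.Series(
        corrected, index=sub.index)
    return SampleTable(out)
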