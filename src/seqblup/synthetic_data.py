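"""Multi-breed / crossbred genotype-phenotype simulator.

Emulates the population structure the prediction pipeline assumes: several
diverged purebred groups plus an F1 cross, local linkage disequilibrium from
founder-haplotype block copying, nested genotyping panels (a 50k-style array
within an HD panel within the full sequence set), a polygenic trait whose
causal variants are partly absent from the array, one categorical fixed
effect, and paternal half-sib families from a small sire pool.

Breed divergence follows the Balding-Nichols model: for ancestral frequency
p and divergence F_ST = F, each breed's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p(1-p).

LD is created mechanically rather than by coalescent simulation: each gamete
copies one founder haplotype per block of ``block_len_bp``, so variants in a
block are perfectly correlated within a founder set and correlation decays
to background across block boundaries.  Offspring gametes recombine parental
haplotypes at block boundaries, so recorded sire/dam links carry real genome
sharing and half-sib families are genuinely related.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (MISSING, GenotypeMatrix, SampleTable, ValidationError,
                         VariantTable)

__all__ = ["SimulationConfig", "TrueGeneticValues", "simulate_breed_frequencies",
           "simulate_population", "ld_profile"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults give a desk-scale caricature of a multi-breed sheep resource:
    two purebred groups plus their F1 cross, moderate breed divergence
    (F_ST = 0.1), ~100 QTL of which 30% are absent from the array panel,
    and a moderately heritable trait (h2 = 0.3, mid-range of the wool/meat
    traits the pipeline is aimed at, which span roughly 0.07-0.68).
    """

    seed: int = 0
    n_breeds: int = 2
    fst: float = 0.10
    #: group name -> count; "B0", "B1", ... are purebreds, "F1_B1xB0" is the
    #: cross with sire breed 1 and dam breed 0 (Border Leicester ram x Merino
    #: ewe style).
    n_per_group: dict = field(default_factory=lambda: {"B0": 500, "B1": 300, "F1_B1xB0": 200})
    n_chrom: int = 3
    chrom_len_bp: int = 1_000_000
    n_seq_variants: int = 3000
    n_hd_variants: int = 1200
    n_array_variants: int = 400
    n_qtl: int = 100
    #: relative variance scales of the non-null effect classes (BayesR-style
    #: mixture); drawn classes are equiprobable.
    qtl_variance_scales: tuple = (1e-4, 1e-3, 1e-2)
    #: fraction of QTL forced off the array panel (but on the sequence panel)
    qtl_off_array_frac: float = 0.30
    h2: float = 0.30
    fixed_effect_levels: int = 4
    fixed_effect_sd: float = 1.0
    block_len_bp: int = 50_000
    n_founder_haplotypes: int = 30
    #: offspring per sire on average; sets half-sib family size
    sire_family_size: int = 10
    #: split breed 0 into this many drifted sub-groups (0 = off); emulates
    #: Merino strain structure (extra Balding-Nichols drift, F_ST = sub_fst)
    n_subgroups: int = 0
    sub_fst: float = 0.02

    def validate(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValidationError("fst must be in (0,1)")
        if not (0.0 < self.h2 <= 1.0):
            raise ValidationError("h2 must be in (0,1]")
        if not (self.n_array_variants <= self.n_hd_variants <= self.n_seq_variants):
            raise ValidationError("panel sizes must nest: array <= HD <= sequence")
        if self.n_qtl > self.n_seq_variants:
            raise ValidationError("more QTL than sequence variants")
        if self.n_seq_variants > self.n_chrom * max(self.chrom_len_bp, 1):
            raise ValidationError("more variants than base pairs")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValidationError(f"negative group size for {g}")
            self._parse_group(g)

    def _parse_group(self, name: str) -> tuple[int, int]:
        """Return (sire_breed, dam_breed); equal for purebreds."""
        if name.startswith("F1_"):
            a, b = name[3:].split("x")
            s, d = int(a[1:]), int(b[1:])
        elif name.startswith("B"):
            s = d = int(name[1:])
        else:
            raise ValidationError(f"group name {name!r} not of form 'B<i>' or 'F1_B<i>xB<j>'")
        if not (0 <= s < self.n_breeds and 0 <= d < self.n_breeds):
            raise ValidationError(f"group {name!r} references a breed >= n_breeds")
        return s, d


@dataclass
class TrueGeneticValues:
    """Simulation ground truth for parameter-recovery tests."""

    tbv: pd.Series            # per-sample true breeding value (index: sample_id)
    effects: pd.Series        # per-variant allele-substitution effect (index: variant_id)
    causal: pd.Series         # per-variant causal flag
    fixed_effects: np.ndarray  # value per fixed-effect level
    realized_h2: float


def simulate_breed_frequencies(p_anc: np.ndarray, fst: float, n_breeds: int,
                               seed) -> np.ndarray:
    """Balding-Nichols per-breed allele frequencies, one row per breed.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (0.0 < fst < 1.0):
        raise ValidationError("fst must be in (0,1)")
    p_anc = np.asarray(p_anc, dtype=float)
    if ((p_anc <= 0) | (p_anc >= 1)).any():
        raise ValidationError("ancestral frequencies must be in (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = (1.0 - fst) / fst
    a = np.broadcast_to(p_anc * lam, (n_breeds, p_anc.size))
    b = np.broadcast_to((1.0 - p_anc) * lam, (n_breeds, p_anc.size))
    freqs = rng.beta(a, b)
    # keep frequencies polymorphic so no panel is degenerate by construction
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _sample_gametes(founders: np.ndarray, block_of: np.ndarray, n_gametes: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Copy one founder haplotype per block for each gamete.

    founders: (n_hap, m) binary; block_of: (m,) block index per variant.
    """
    n_hap = founders.shape[0]
    n_blocks = block_of.max() + 1
    choice = rng.integers(0, n_hap, size=(n_gametes, n_blocks))
    return founders[choice[:, block_of], np.arange(block_of.size)]


def _recombine(hap_a: np.ndarray, hap_b: np.ndarray, block_of: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes, switching at block edges."""
    n_blocks = block_of.max() + 1
    pick = rng.integers(0, 2, size=n_blocks)[block_of].astype(bool)
    return np.where(pick, hap_a, hap_b)


def simulate_population(cfg: SimulationConfig):
    """Simulate genotypes, sample records and ground truth.

    Returns ``(GenotypeMatrix, SampleTable, TrueGeneticValues)``.  All
    randomness flows from ``cfg.seed`` through one generator, so identical
    configs give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_seq_variants

    # --- variant map: positions uniform per chromosome, panels by thinning
    per_chrom = np.full(cfg.n_chrom, m // cfg.n_chrom)
    per_chrom[: m % cfg.n_chrom] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_len_bp, size=per_chrom[c], replace=False)) + 1
        positions.append(pos)
        chroms.append(np.full(per_chrom[c], str(c + 1)))
    chrom = np.concatenate(chroms)
    pos_bp = np.concatenate(positions)
    variant_id = np.array([f"chr{c}:{p}" for c, p in zip(chrom, pos_bp)])

    hd_idx = np.unique(np.linspace(0, m - 1, cfg.n_hd_variants).round().astype(int))
    array_idx = hd_idx[np.unique(np.linspace(0, hd_idx.size - 1,
                                             cfg.n_array_variants).round().astype(int))]
    on_hd = np.zeros(m, dtype=bool); on_hd[hd_idx] = True
    on_array = np.zeros(m, dtype=bool); on_array[array_idx] = True

    vt = VariantTable(pd.DataFrame({
        "variant_id": variant_id, "chrom": chrom, "pos_bp": pos_bp,
        "allele_a1": "A", "allele_a2": "G",
        "ARRAY50K": on_array, "HD": on_hd, "WGS": True,
    }))

    # --- breed frequencies and founder haplotypes
    p_anc = rng.uniform(0.05, 0.95, size=m)
    breed_freq = simulate_breed_frequencies(p_anc, cfg.fst, cfg.n_breeds, rng)
    # blocks are global bp windows, numbered within chromosome
    block_of = np.zeros(m, dtype=np.int64)
    offset = 0
    for c in range(cfg.n_chrom):
        sel = chrom == str(c + 1)
        blk = (pos_bp[sel] - 1) // cfg.block_len_bp
        block_of[sel] = blk + offset
        offset += blk.max() + 1 if sel.any() else 0
    # renumber to occupied blocks only (block_len can be far below the
    # inter-variant spacing, e.g. when simulating free recombination)
    _, block_of = np.unique(block_of, return_inverse=True)

    n_sub = max(cfg.n_subgroups, 0)
    founder_sets: dict[tuple[int, int], np.ndarray] = {}

    def founders_for(breed: int, sub: int) -> np.ndarray:
        key = (breed, sub)
        if key not in founder_sets:
            freq = breed_freq[breed]
            if breed == 0 and n_sub > 0:
                freq = simulate_breed_frequencies(freq, cfg.sub_fst, 1, rng)[0]
            founder_sets[key] = (rng.random((cfg.n_founder_haplotypes, m))
                                 < freq).astype(np.int8)
        return founder_sets[key]

    # --- parent generation: sires and dams per (breed, subgroup)
    groups = list(cfg.n_per_group.items())
    n_total = sum(n for _, n in groups)
    need_parents: dict[tuple[int, int], int] = {}

    def subgroup_of(breed: int, rng) -> int:
        return int(rng.integers(0, n_sub)) if (breed == 0 and n_sub > 0) else 0

    # pre-assign each offspring its group and (for breed-0) subgroup
    offspring_plan = []
    for gname, n_g in groups:
        sb, db = cfg._parse_group(gname)
        for _ in range(n_g):
            offspring_plan.append((gname, sb, db, subgroup_of(sb, rng), subgroup_of(db, rng)))

    # sire pools sized for half-sib families; dams individual
    pool_need: dict[tuple[int, int], int] = {}
    for _, sb, _db, ssub, _dsub in offspring_plan:
        pool_need[(sb, ssub)] = pool_need.get((sb, ssub), 0) + 1
    sire_pools = {}
    for key, n_off in pool_need.items():
        n_sires = max(1, int(np.ceil(n_off / cfg.sire_family_size)))
        founders = founders_for(*key)
        haps = _sample_gametes(founders, block_of, 2 * n_sires, rng)
        sire_pools[key] = (haps[0::2], haps[1::2])

    # --- offspring genotypes
    dosage = np.empty((n_total, m), dtype=np.int8)
    rows = []
    sire_counter: dict[tuple[int, int], int] = {k: 0 for k in sire_pools}
    for i, (gname, sb, db, ssub, dsub) in enumerate(offspring_plan):
        key = (sb, ssub)
        hap_a, hap_b = sire_pools[key]
        s_idx = int(rng.integers(0, hap_a.shape[0]))
        paternal = _recombine(hap_a[s_idx], hap_b[s_idx], block_of, rng)
        dam_founders = founders_for(db, dsub)
        dam_haps = _sample_gametes(dam_founders, block_of, 2, rng)
        maternal = _recombine(dam_haps[0], dam_haps[1], block_of, rng)
        dosage[i] = paternal + maternal
        props = np.zeros(cfg.n_breeds)
        props[sb] += 0.5
        props[db] += 0.5
        rows.append({
            "sample_id": f"{gname}_{i:05d}",
            "sire_id": f"SIRE_B{sb}s{ssub}_{s_idx:03d}",
            "dam_id": f"DAM_{i:05d}",
            "group": gname,
            "subgroup": f"sub{ssub}" if (sb == db == 0 and n_sub > 0) else ".",
            **{f"breed_{b}": props[b] for b in range(cfg.n_breeds)},
        })
    samples_df = pd.DataFrame(rows)

    # --- QTL placement: a fraction forced off the array panel
    n_off = int(round(cfg.qtl_off_array_frac * cfg.n_qtl))
    off_pool = np.flatnonzero(~on_array)
    on_pool = np.flatnonzero(on_array)
    n_off = min(n_off, off_pool.size)
    n_on = min(cfg.n_qtl - n_off, on_pool.size)
    qtl_idx = np.concatenate([
        rng.choice(off_pool, size=n_off, replace=False),
        rng.choice(on_pool, size=n_on, replace=False),
    ])
    qtl_idx.sort()

    # --- effects from the variance-scale mixture
    scales = np.asarray(cfg.qtl_variance_scales, dtype=float)
    cls = rng.integers(0, scales.size, size=qtl_idx.size)
    effects = np.zeros(m)
    effects[qtl_idx] = rng.normal(0.0, np.sqrt(scales[cls]))
    causal = np.zeros(m, dtype=bool)
    causal[qtl_idx] = True

    tbv = dosage.astype(np.float64) @ effects
    var_tbv = tbv.var()
    if var_tbv == 0.0:
        var_tbv = 1.0  # degenerate: no genetic variance; noise still defined

    # --- phenotype: fixed effect + TBV + residual noise at the target h2
    levels = rng.integers(0, cfg.fixed_effect_levels, size=n_total)
    level_effects = rng.normal(0.0, cfg.fixed_effect_sd, size=cfg.fixed_effect_levels)
    sigma_e = np.sqrt(var_tbv * (1.0 - cfg.h2) / cfg.h2)
    noise = rng.normal(0.0, sigma_e, size=n_total) if sigma_e > 0 else np.zeros(n_total)
    phenotype = level_effects[levels] + tbv + noise
    denom = np.var(tbv + noise)
    realized_h2 = float(var_tbv / denom) if denom > 0 else 1.0

    samples_df["data_source"] = [f"src{lv}" for lv in levels]
    samples_df["phenotype"] = phenotype
    samples_df["corrected_phenotype"] = np.nan
    samples_df["role"] = "UNUSED"

    geno = GenotypeMatrix(samples_df["sample_id"].tolist(), vt, dosage)
    table = SampleTable(samples_df)
    truth = TrueGeneticValues(
        tbv=pd.Series(tbv, index=samples_df["sample_id"]),
        effects=pd.Series(effects, index=variant_id),
        causal=pd.Series(causal, index=variant_id),
        fixed_effects=level_effects,
        realized_h2=realized_h2,
    )
    return geno, table, truth


def ld_profile(g: GenotypeMatrix, max_dist_bp: int, n_bins: int = 10,
               max_pairs: int = 200_000, seed: int = 0) -> pd.DataFrame:
    """Mean r^2 between variant pairs binned by distance.

    Pairs are enumerated per chromosome up to ``max_dist_bp`` apart and
    subsampled to ``max_pairs`` for tractability.  Returns a table with
    columns dist_lo, dist_hi, n_pairs, mean_r2.
    """
    if g.n_variants < 2:
        raise ValidationError("need at least two variants for an LD profile")
    rng = np.random.default_rng(seed)
    x = g.dosage_float(impute_mean=True)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    pairs = []
    df = g.variants.df
    for _chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy()
        for k, i in enumerate(idx):
            right = idx[(pos > pos[k]) & (pos <= pos[k] + max_dist_bp)]
            for j in right:
                if ok[i] and ok[j]:
                    pairs.append((i, j, df["pos_bp"].iloc[j] - pos[k]))
    pairs = np.array(pairs, dtype=np.int64).reshape(-1, 3)
    if pairs.shape[0] > max_pairs:
        pairs = pairs[rng.choice(pairs.shape[0], size=max_pairs, replace=False)]
    if pairs.shape[0] == 0:
        return pd.DataFrame(columns=["dist_lo", "dist_hi", "n_pairs", "mean_r2"])
    r = (x[:, pairs[:, 0]] * x[:, pairs[:, 1]]).mean(axis=0) / (sd[pairs[:, 0]] * sd[pairs[:, 1]])
    r2 = r ** 2
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.searchsorted(edges, pairs[:, 2], side="right") - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            out.append({"dist_lo": edges[b], "dist_hi": edges[b + 1],
                        "n_pairs": int(sel.sum()), "mean_r2": float(r2[sel].mean())})
    return pd.DataFrame(out)
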