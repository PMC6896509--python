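"""End-to-end orchestration: simulate -> split -> GWAS -> select -> predict.

One seeded :class:`RunConfig` drives every stage; every artifact is written
under the run directory and checksummed into ``manifest.json``, so a rerun
with the same config reproduces the checksums of all deterministic stages.
Stage defaults are the standard operating point of the analysis: 100-kb
windows sliding by 50 kb, p < 1e-3, r^2 pruning at 0.95, MAF 0.005,
relationship threshold 0.25, discovery fraction 0.30, and 5 MCMC chains of
40,000 iterations (20,000 burn-in).  Tests and examples scale the MCMC and
population sizes down.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesr as br
from . import evaluation, grm, gwas, io_formats, study_design, variant_selection
from . import greml_gblup as gg
from .synthetic_data import SimulationConfig, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    out_dir: str = "seqblup_run"
    # variant selection
    window_bp: int = 100_000
    step_bp: int = 50_000
    p_thresh: float = 1e-3
    r2_max: float = 0.95
    maf_min: float = 0.005
    # study design
    discovery_frac: float = 0.30
    grm_threshold: float = 0.25
    validation_frac: float = 0.5
    validation_groups: tuple | None = None  # default: first purebred + first F1
    # MCMC
    n_iter: int = 40_000
    n_burnin: int = 20_000
    n_chains: int = 5
    thin: int = 10
    #: scenarios to run (subset of evaluation.SCENARIOS); None = all
    scenarios: tuple | None = None

    def validate(self) -> None:
        self.sim.validate()
        if not (0 < self.discovery_frac < 1):
            raise ValueError("discovery_frac must be in (0,1)")
        if not (0 < self.p_thresh <= 1):
            raise ValueError("p_thresh must be in (0,1]")
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must be in [0,1]")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        bad = set(self.scenarios or ()) - set(evaluation.SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of in-memory results and writes the
    artifact manifest.  Any stage failure raises :class:`StageFailure`
    naming the stage."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    results: dict = {"out_dir": str(out)}

    def record(stage: str, params: dict, files: list[Path], counts: dict = None):
        manifest["stages"][stage] = {
            "params": params,
            "counts": counts or {},
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        g, samples, truth = simulate_population(sim)
        io_formats.write_plink(g, out / "genotypes")
        io_formats.write_samples(samples, out / "samples.tsv")
        io_formats.write_table(
            pd.DataFrame({"variant_id": truth.effects.index,
                          "effect": truth.effects.to_numpy(),
                          "causal": truth.causal.to_numpy()}),
            out / "truth_effects.tsv")
        record(stage, {"seed": cfg.seed},
               [out / f"genotypes{s}" for s in (".bed", ".bim", ".fam")]
               + [out / "samples.tsv", out / "truth_effects.tsv"],
               {"n_samples": g.n_samples, "n_variants": g.n_variants})
    except Exception as e:  # noqa: BLE001 - halt with the stage name
        raise StageFailure(stage, e) from e
    results.update(genotypes=g, samples=samples, truth=truth)

    # -- GRMs for design and reference h2 ----------------------------------
    stage = "grm"
    try:
        grm_array = grm.compute_grm(g, "ARRAY50K", cfg.maf_min)
        grm_hd = grm.compute_grm(g, "HD", cfg.maf_min)
        grm_array.to_gcta(out / "grm_array")
        record(stage, {"maf_min": cfg.maf_min},
               [out / "grm_array.grm.bin", out / "grm_array.grm.id"],
               {"array_m": grm_array.n_variants_used, "hd_m": grm_hd.n_variants_used})
    except Exception as e:
        raise StageFailure(stage, e) from e

    # -- split + precorrect -------------------------------------------------
    stage = "split"
    try:
        groups = cfg.validation_groups
        if groups is None:
            names = list(cfg.sim.n_per_group)
            pure = next(n for n in names if not n.startswith("F1_"))
            f1 = next((n for n in names if n.startswith("F1_")), None)
            groups = tuple(x for x in (pure, f1) if x)
        split = study_design.partition(
            samples, grm_array, cfg.discovery_frac, cfg.grm_threshold,
            validation_groups=groups, validation_frac=cfg.validation_frac,
            seed=cfg.seed + 1)
        samples = study_design.precorrect(samples, grm_hd)
        samples = samples.with_roles(split.roles)
        io_formats.write_table(split.to_frame(), out / "roles.tsv")
        (out / "split_audit.json").write_text(json.dumps(split.audit, indent=1))
        io_formats.write_samples(samples, out / "samples_corrected.tsv")
        record(stage, {"discovery_frac": cfg.discovery_frac,
                       "grm_threshold": cfg.grm_threshold,
                       "validation_groups": list(groups)},
               [out / "roles.tsv", out / "split_audit.json",
                out / "samples_corrected.tsv"],
               {r: len(split.ids(r)) for r in io_formats.SAMPLE_ROLES})
    except Exception as e:
        raise StageFailure(stage, e) from e
    results.update(split=split, samples=samples)

    disc_ids = split.ids("DISCOVERY")
    train_ids = split.ids("TRAINING")
    val_ids = split.ids("VALIDATION")

    # -- GWAS in the discovery set ------------------------------------------
    stage = "gwas"
    try:
        g_disc = g.subset(sample_ids=disc_ids)
        grm_disc_hd = grm.compute_grm(g_disc, "HD", cfg.maf_min)
        y_d, X_d, Q_d = gwas.design_matrices(samples, ids=disc_ids)
        null_fit = gwas.fit_null_mixed_model(y_d, X_d, Q_d, grm_disc_hd,
                                             sample_ids=disc_ids)
        scan = gwas.gwas_scan(g_disc, null_fit, maf_min=cfg.maf_min)
        io_formats.write_table(scan.table.drop(columns=["reason"]),
                               out / "gwas.tsv")
        record(stage, {"maf_min": cfg.maf_min, "grm_panel": "HD"},
               [out / "gwas.tsv"],
               {"n_discovery": len(disc_ids),
                "n_tested": int(scan.table["p_value"].notna().sum())})
    except Exception as e:
        raise StageFailure(stage, e) from e
    results.update(null_fit=null_fit, scan=scan)

    # -- top-SNP selection ---------------------------------------------------
    stage = "select"
    try:
        g_train = g.subset(sample_ids=train_ids)
        tops = variant_selection.select_top_snps(
            scan, g_disc, g_train, cfg.window_bp, cfg.step_bp,
            cfg.p_thresh, cfg.r2_max, cfg.maf_min)
        array_ids = set(g.variants.ids[g.variants.panel_mask("ARRAY50K")])
        tops, array_joint = variant_selection.harmonize_with_array(tops, array_ids)
        io_formats.write_variant_ids(tops.variant_ids, out / "top_snps.txt")
        io_formats.write_table(pd.DataFrame(tops.removed,
                                            columns=["variant_id", "reason"]),
                               out / "top_snp_removals.tsv")
        record(stage, {"window_bp": cfg.window_bp, "step_bp": cfg.step_bp,
                       "p_thresh": cfg.p_thresh, "r2_max": cfg.r2_max,
                       "maf_min": cfg.maf_min},
               [out / "top_snps.txt", out / "top_snp_removals.tsv"],
               {"n_top": len(tops), "n_removed": len(tops.removed),
                "n_array_overlap_moved": len(array_ids) - len(array_joint)})
    except Exception as e:
        raise StageFailure(stage, e) from e
    results.update(tops=tops)

    # -- prediction scenarios -----------------------------------------------
    stage = "predict"
    scen = tuple(cfg.scenarios or evaluation.SCENARIOS)
    try:
        vids = g.variants.ids
        id_to_col = {v: i for i, v in enumerate(vids)}
        top_mask = np.zeros(len(vids), dtype=bool)
        top_mask[[id_to_col[v] for v in tops.variant_ids]] = True
        masks = {
            "top": top_mask,
            "50k": g.variants.panel_mask("ARRAY50K"),
            "HD": g.variants.panel_mask("HD"),
            "WGS": g.variants.panel_mask("WGS"),
        }
        joint_mask = np.zeros(len(vids), dtype=bool)
        joint_mask[[id_to_col[v] for v in array_joint]] = True
        masks["50k+top"] = joint_mask | top_mask

        # MAF filter in the prediction training population applies to every
        # genotype set
        maf_train = g.subset(sample_ids=train_ids).maf()
        maf_ok = maf_train >= cfg.maf_min
        masks = {k: v & maf_ok for k, v in masks.items()}

        pv = train_ids + val_ids
        g_pv = g.subset(sample_ids=pv)
        y_train = samples.df.set_index("sample_id").loc[
            train_ids, "corrected_phenotype"].to_numpy(float)

        grms: dict[str, grm.GRM] = {}

        def get_grm(name):
            if name not in grms:
                gm = grm.compute_grm(g_pv, name, cfg.maf_min,
                                     variant_mask=masks[name])
                gm.panel_name = name
                grms[name] = gm
            return grms[name]

        gbv_by_method: dict = {}
        fits: dict = {}

        def gblup_scenario(label, panel_names):
            gl = [get_grm(p) for p in panel_names]
            vc = gg.greml(y_train, gl, sample_ids=train_ids)
            fit = gg.gblup_predict(y_train, vc, gl, train_ids, val_ids)
            fits[label] = fit
            gbv_by_method[label] = fit.gbv["gbv_total"]

        # reference h2 from the array panel, used to scale every accuracy
        vc_ref = gg.greml(y_train, [get_grm("50k")], sample_ids=train_ids)
        h2_ref = gg.heritability(vc_ref)["total"]
        fits["h2_ref_vc"] = vc_ref

        if "GBLUP-top" in scen and len(tops):
            gblup_scenario("GBLUP-top", ["top"])
        if "GBLUP-50k" in scen:
            gblup_scenario("GBLUP-50k", ["50k"])
        if "GBLUP-50k+top-1GRM" in scen:
            gblup_scenario("GBLUP-50k+top-1GRM", ["50k+top"])
        if "2GBLUP" in scen and len(tops):
            gblup_scenario("2GBLUP", ["50k", "top"])
        if "GBLUP-HD" in scen:
            gblup_scenario("GBLUP-HD", ["HD"])
        if "GBLUP-WGS" in scen:
            gblup_scenario("GBLUP-WGS", ["WGS"])

        bayes_panels = {"BayesR-top": "top", "BayesR-50k": "50k",
                        "BayesR-50k+top": "50k+top", "BayesR-HD": "HD"}
        for label, panel in bayes_panels.items():
            if label not in scen or (panel == "top" and not len(tops)):
                continue
            std = br.standardize(g, train_ids, variant_mask=masks[panel])
            model = br.bayesr_fit(y_train, std.matrix(train_ids),
                                  std.variant_ids, n_iter=cfg.n_iter,
                                  n_burnin=cfg.n_burnin, n_chains=cfg.n_chains,
                                  seed=cfg.seed + 17, thin=cfg.thin)
            gbv = br.bayes_predict(model, std.matrix(val_ids))
            gbv.index = pd.Index(val_ids, name="sample_id")
            fits[label] = model
            gbv_by_method[label] = gbv
        if "BayesRC" in scen and len(tops):
            std = br.standardize(g, train_ids, variant_mask=masks["50k+top"])
            top_set = set(tops.variant_ids)
            cats = {v: ("top" if v in top_set else "array")
                    for v in std.variant_ids}
            model = br.bayesrc_fit(y_train, std.matrix(train_ids),
                                   std.variant_ids, cats, n_iter=cfg.n_iter,
                                   n_burnin=cfg.n_burnin, n_chains=cfg.n_chains,
                                   seed=cfg.seed + 17, thin=cfg.thin)
            gbv = br.bayes_predict(model, std.matrix(val_ids))
            gbv.index = pd.Index(val_ids, name="sample_id")
            fits["BayesRC"] = model
            gbv_by_method["BayesRC"] = gbv
        record(stage, {"scenarios": list(scen), "n_iter": cfg.n_iter,
                       "n_burnin": cfg.n_burnin, "n_chains": cfg.n_chains},
               [], {"h2_ref": h2_ref})
    except Exception as e:
        raise StageFailure(stage, e) from e
    results.update(fits=fits, gbv_by_method=gbv_by_method, h2_ref=h2_ref)

    # -- evaluation -----------------------------------------------------------
    stage = "evaluate"
    try:
        sdf = samples.df.set_index("sample_id")
        y_by_group = {}
        for gname in groups:
            ids = [v for v in val_ids if sdf.loc[v, "group"] == gname] \
                if "group" in sdf.columns else val_ids
            if ids:
                y_by_group[gname] = sdf.loc[ids, "corrected_phenotype"]
        grid = evaluation.method_grid(gbv_by_method, y_by_group, h2_ref,
                                      scenarios=scen)
        io_formats.write_table(grid, out / "results.tsv")
        record(stage, {"h2_ref": h2_ref}, [out / "results.tsv"],
               {"n_rows": len(grid)})
    except Exception as e:
        raise StageFailure(stage, e) from e
    results["grid"] = grid

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
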