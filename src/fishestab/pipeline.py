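"""Orchestrated, seeded, logged end-to-end analysis runs.

A run takes either the four input files (records, lakes, communities,
traits + Newick tree) or a synthetic-data configuration, computes the
distance matrices and per-event covariates, and executes the requested
model stages: the phylogenetic Bayesian hierarchical model (for the mean
and/or nearest metric family, compared by WAIC), the all-subsets GLMM
AICc average, and the piecewise SEM (geography and/or temperature
variant).  Every artifact is written with a manifest of content hashes
and stage seeds; a JSON-lines log records stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, hiermodel, io, modelavg, sem as sem_mod
from .distances import (
    build_dendrogram,
    cophenetic_distances,
    dendrogram_to_newick,
    functional_distances,
    mantel_test,
    trait_pca,
)
from .metrics import MEAN_PREDICTORS, NEAREST_PREDICTORS, assemble_covariates
from .synth import SynthConfig, generate

__all__ = ["RunConfig", "RunReport", "run"]


@dataclass
class RunConfig:
    outdir: str = "fishestab_run"
    seed: int = 0
    synth: SynthConfig | None = None            # exclusive with input_paths
    input_paths: dict | None = None             # records/lakes/communities/traits/tree
    io_config: io.IOConfig = field(default_factory=io.IOConfig)
    metric_families: tuple[str, ...] = ("mean", "nearest")
    stages: tuple[str, ...] = ("hier", "modelavg", "sem")
    sem_variants: tuple[str, ...] = ("geography",)
    linkage: str = "complete"
    n_draws: int = 1000
    mantel_permutations: int = 999

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage must be enabled")
        if (self.synth is None) == (self.input_paths is None):
            if self.synth is None:
                self.synth = SynthConfig(seed=self.seed)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "io_config" in raw:
            raw["io_config"] = io.IOConfig(**raw["io_config"])
        for key in ("metric_families", "stages", "sem_variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    report: dict
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    log_fh = open(log_path, "w")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": {}, "files": {}, "timings": {}}
    report: dict = {"stages_run": [], "stages_skipped": [], "partial": False}

    def log(stage: str, **info) -> None:
        log_fh.write(json.dumps({"t": time.time(), "stage": stage, **info}) + "\n")
        log_fh.flush()

    def register(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ("synth", "mantel", "hier_mean", "hier_nearest", "sem"), ss.spawn(5)
        )
    }
    manifest["stage_seeds"] = stage_seed

    t0 = time.time()
    # ------------------------------------------------------------------ inputs
    if config.synth is not None:
        # all randomness flows from the single run seed
        synth_cfg = SynthConfig(**{**config.synth.__dict__, "seed": stage_seed["synth"]})
        data = generate(synth_cfg)
        input_dir = outdir / "inputs"
        for name, p in data.write_inputs(input_dir).items():
            register(f"input_{name}", Path(p))
        bundle = io.InputBundle(
            records=data.records, lakes=data.lakes, communities=data.communities,
            traits=data.traits, tree=data.tree,
        )
        log("synth", n_events=len(data.records), seed=synth_cfg.seed)
    else:
        bundle = io.read_inputs(config=config.io_config, **config.input_paths)
        log("read_inputs", **{k: len(v) for k, v in
                              [("records", bundle.records), ("lakes", bundle.lakes)]})
    bundle, filter_log = io.apply_filters(bundle, config.io_config)
    filter_log.to_json(outdir / "filter_log.json")
    register("filter_log", outdir / "filter_log.json")
    if "depth" in bundle.lakes.columns:
        imput = io.impute_water_temperature(bundle.lakes)
        bundle.lakes = imput.lakes
        report["imputation"] = imput.stages
    manifest["timings"]["inputs"] = time.time() - t0

    # --------------------------------------------------------------- distances
    t0 = time.time()
    d_phy = cophenetic_distances(bundle.tree)
    space = trait_pca(bundle.traits)
    d_fun = functional_distances(space)
    dist_dir = outdir / "distances"
    dist_dir.mkdir(exist_ok=True)
    d_phy.to_csv(dist_dir / "phylogenetic.csv")
    d_fun.to_csv(dist_dir / "functional.csv")
    Z, labels = build_dendrogram(d_fun, method=config.linkage)
    (dist_dir / "functional_dendrogram.nwk").write_text(
        dendrogram_to_newick(Z, labels) + "\n")
    for f in dist_dir.iterdir():
        register(f"distances_{f.stem}", f)
    mres = mantel_test(
        d_phy, d_fun.submatrix(d_phy.species),
        n_perm=config.mantel_permutations, seed=stage_seed["mantel"],
    )
    report["phylogenetic_signal"] = {"mantel_r": mres.r, "mantel_p": mres.p}
    report["pca_explained_variance_ratio"] = space.explained_variance_ratio.tolist()
    log("distances", mantel_r=mres.r, mantel_p=mres.p)
    manifest["timings"]["distances"] = time.time() - t0

    # ----------------------------------------------------------------- metrics
    t0 = time.time()
    table = assemble_covariates(
        bundle.records, bundle.lakes, bundle.community_sets(), d_phy, d_fun
    )
    df = table.data
    df.to_csv(outdir / "covariates.csv", index=False)
    register("covariates", outdir / "covariates.csv")
    report["n_events_modeled"] = int(len(df))
    report["n_events_dropped"] = len(table.dropped)
    report["establishment_rate"] = float(df["outcome"].mean())
    log("metrics", n=len(df), dropped=len(table.dropped))
    manifest["timings"]["metrics"] = time.time() - t0

    family_preds = {"mean": MEAN_PREDICTORS, "nearest": NEAREST_PREDICTORS}

    # ----------------------------------------------------------------- hier
    hier_fits = {}
    if "hier" in config.stages:
        t0 = time.time()
        introduced = sorted(df["species_id"].astype(str).unique())
        phylo = hiermodel.phylo_covariance(bundle.tree, introduced)
        waic_tab = {}
        for fam in config.metric_families:
            fit = hiermodel.fit_hier(
                df, family_preds[fam], phylo, n_draws=config.n_draws,
                seed=stage_seed[f"hier_{fam}"],
            )
            hier_fits[fam] = fit
            waic_tab[fam] = fit.waic
            payload = {
                "family": fam,
                "summary": fit.summary.round(6).to_dict(orient="index"),
                "sigma": fit.sigma,
                "waic": fit.waic,
                "p_waic": fit.p_waic,
                "relative_importance": hiermodel.relative_importance(fit).to_dict(),
                "grouped_importance": hiermodel.grouped_importance(fit).to_dict(),
                "converged": fit.converged,
                "diagnostics": fit.diagnostics,
            }
            path = outdir / f"hier_{fam}.json"
            path.write_text(json.dumps(payload, indent=2))
            register(f"hier_{fam}", path)
            log("hier", family=fam, waic=fit.waic)
        report["waic"] = waic_tab
        if len(waic_tab) == 2:
            report["waic_diff_nearest_minus_mean"] = (
                waic_tab["nearest"] - waic_tab["mean"]
            )
        fam0 = config.metric_families[0]
        report["hier"] = {
            fam: {
                "coefficients": {p: hier_fits[fam].coef_mean(p)
                                 for p in family_preds[fam]},
                "ci95": {p: hier_fits[fam].ci(p) for p in family_preds[fam]},
                "grouped_importance": hiermodel.grouped_importance(hier_fits[fam]).to_dict(),
            }
            for fam in hier_fits
        }
        report["stages_run"].append("hier")
        manifest["timings"]["hier"] = time.time() - t0
    else:
        report["stages_skipped"].append("hier")

    # -------------------------------------------------------------- modelavg
    if "modelavg" in config.stages:
        t0 = time.time()
        fam = config.metric_families[0]
        preds_z = [p + "_z" for p in family_preds[fam]]
        records = modelavg.dredge(df, preds_z)
        modelavg.records_to_frame(records).to_csv(
            outdir / "modelavg_models.csv", index=False)
        register("modelavg_models", outdir / "modelavg_models.csv")
        avg = modelavg.model_average(records, preds_z)
        pd.DataFrame({"coef": avg.coef, "se": avg.se}).to_csv(
            outdir / "modelavg_coefficients.csv", index_label="term")
        register("modelavg_coefficients", outdir / "modelavg_coefficients.csv")
        report["modelavg"] = {
            "family": fam,
            "n_models_averaged": avg.n_models,
            "coefficients": avg.coef.to_dict(),
            "best_subset": "+".join(records[0].subset),
        }
        report["stages_run"].append("modelavg")
        log("modelavg", n_models=len(records), averaged=avg.n_models)
        manifest["timings"]["modelavg"] = time.time() - t0
    else:
        report["stages_skipped"].append("modelavg")

    # --------------------------------------------------------------------- sem
    if "sem" in config.stages:
        t0 = time.time()
        fam = config.metric_families[0]
        report["sem"] = {}
        for variant in config.sem_variants:
            sem_df = df.copy()
            needed = (
                ["accum_temp", "max_temp"] if variant == "temperature" else []
            )
            if any(c not in sem_df.columns for c in needed):
                report["sem"][variant] = {"skipped": "temperature fields unavailable"}
                continue
            dag = sem_mod.default_dag(variant=variant, family=fam)
            families = {"outcome": "bernoulli"}
            fit, ledger = sem_mod.sem_selection(
                dag, sem_df, families, factor_cols=["lake_id", "species_id"]
            )
            effects = sem_mod.effects_decomposition(fit, target="outcome")
            fit.edges.to_csv(outdir / f"sem_{variant}_edges.csv", index=False)
            effects.table.to_csv(outdir / f"sem_{variant}_effects.csv")
            payload = {
                "fisher_c": fit.dsep.fisher_c,
                "df": fit.dsep.df,
                "p_global": fit.dsep.p_global,
                "K": fit.dsep.k_params,
                "aic": fit.dsep.aic,
                "n": int(len(sem_df)),
                "r2c": fit.r2c,
                "selection": ledger,
            }
            (outdir / f"sem_{variant}.json").write_text(json.dumps(payload, indent=2))
            for suffix in ("edges.csv", "effects.csv"):
                register(f"sem_{variant}_{suffix}", outdir / f"sem_{variant}_{suffix}")
            register(f"sem_{variant}", outdir / f"sem_{variant}.json")
            direct = {
                r.source: r.beta_std
                for r in fit.edges.itertuples(index=False) if r.target == "outcome"
            }
            report["sem"][variant] = {**payload, "direct_std": direct,
                                      "effects": effects.table.to_dict(orient="index")}
            log("sem", variant=variant, C=fit.dsep.fisher_c, aic=fit.dsep.aic)
        report["stages_run"].append("sem")
        manifest["timings"]["sem"] = time.time() - t0
    else:
        report["stages_skipped"].append("sem")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log_fh.close()
    return RunReport(report=report, manifest=manifest, outdir=outdir)
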