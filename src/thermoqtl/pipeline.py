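"""End-to-end orchestration: simulate (or load) -> spatially adjusted BLUPs
-> QTL scan -> genomic prediction -> rank-sum selection.

A pipeline run is driven by a single YAML/dict config with one global seed;
per-stage child seeds are derived with numpy's SeedSequence spawning so
stages are independently reproducible.  Every run writes a manifest
(parameters, outputs, per-stage status) even on partial failure; a stage
failure halts downstream stages but preserves upstream outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gs as gs_mod
from . import qtl as qtl_mod
from . import selection as sel_mod
from . import simulate as sim
from . import trial as trial_mod
from .errors import ConfigError, DataError, ThermoQtlError
from .genmap import GeneticMap

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline", "validate_io"]

def _default_simulate_section() -> dict:
    """Serializable form of the canonical study conditions."""
    cond = sim.study_conditions()
    return {
        "map": dict(cond["map"]),
        "population": dict(cond["population"]),
        "layout": dict(cond["layout"]),
        "environments": list(cond["environments"]),
        "traits": list(cond["traits"]),
        "variance": {
            t: {
                "genotype_var": v.genotype_var,
                "row_var": v.row_var,
                "column_var": v.column_var,
                "residual_var": v.residual_var,
                "trait_means": dict(v.trait_means),
                "turgor_cutpoints": list(v.turgor_cutpoints),
            }
            for t, v in cond["variance"].items()
        },
        "qtls": [vars(q) for q in cond["qtls"]],
    }


DEFAULT_CONFIG = {
    "seed": 11,
    "simulate": _default_simulate_section(),
    "trial": {"traits": ["turgor", "canopy_temp"]},
    "qtl": {"step": 2.0, "window": 40.0, "n_cofactors": 1, "n_perm": 200, "alpha": 0.05},
    "gs": {"loo": False},
    "select": {"n_pheno": 10, "n_gs": 10, "n_random": 10},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    return validate_config(cfg)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    """Fill defaults and check the config before any stage runs."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - set(DEFAULT_CONFIG) - {"inputs", "outdir"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    merged = _merge(DEFAULT_CONFIG, {k: v for k, v in cfg.items() if k != "inputs"})
    if "inputs" in cfg:
        merged["inputs"] = dict(cfg["inputs"])
        for key, p in merged["inputs"].items():
            if not Path(p).exists():
                raise ConfigError(f"inputs.{key}: file not found: {p}")
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed must be an integer (mandatory for stochastic stages)")
    q = merged["qtl"]
    if q["n_perm"] < 100:
        raise ConfigError("qtl.n_perm must be >= 100")
    if not (0 < q["alpha"] <= 1):
        raise ConfigError("qtl.alpha must lie in (0, 1]")
    return merged


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds spawned from the global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config, outdir) -> dict:
    """Execute the configured stages in dependency order; returns and
    writes the run manifest."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(["simulate", "qtl", "select"], _child_seeds(cfg["seed"], 3)))
    manifest = {"config": cfg, "stages": {}, "outputs": {}}

    def record(stage, status, t0, **extra):
        manifest["stages"][stage] = {
            "status": status, "seconds": round(time.time() - t0, 2), **extra,
        }

    try:
        _run_stages(cfg, outdir, seeds, manifest, record)
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stages(cfg, outdir, seeds, manifest, record):
    # -- stage 1: simulate or load inputs ---------------------------------
    t0 = time.time()
    try:
        if "inputs" in cfg:
            gmap = GeneticMap.from_csv(cfg["inputs"]["map"])
            pop = sim.PopulationGenotypes.from_csv(cfg["inputs"]["genotypes"])
            pheno = pd.read_csv(cfg["inputs"]["phenotypes"])
        else:
            s = cfg["simulate"]
            cond = {
                "map": s["map"],
                "population": s["population"],
                "layout": s["layout"],
                "environments": s["environments"],
                "traits": s["traits"],
                "variance": {
                    t: sim.VarianceSpec(**v) for t, v in s["variance"].items()
                },
                "qtls": [sim.QtlEffect(**q) for q in s["qtls"]],
            }
            study = sim.simulate_study(seeds["simulate"], cond)
            gmap, pop, pheno = study["map"], study["population"], study["phenotypes"]
            gmap.to_csv(outdir / "map.csv")
            pop.to_csv(outdir / "genotypes.csv")
            pheno.to_csv(outdir / "phenotypes.csv", index=False)
            manifest["outputs"].update(
                map="map.csv", genotypes="genotypes.csv", phenotypes="phenotypes.csv"
            )
        record("simulate", "ok", t0, n_lines=pop.n_lines, n_markers=len(pop.markers))
    except ThermoQtlError as exc:
        record("simulate", "error", t0, message=str(exc))
        raise

    # -- stage 2: trial models -> averaged BLUPs --------------------------
    t0 = time.time()
    traits = cfg["trial"]["traits"]
    try:
        blups = {}
        vcs = {}
        for trait in traits:
            per_env = {}
            for env, sub in pheno.groupby("environment"):
                res = trial_mod.TrialModel(sub.reset_index(drop=True), trait).fit()
                per_env[env] = res.blups
                vcs[f"{trait}/{env}"] = {
                    **res.variance_components, "residual": res.resid_variance,
                }
            blups[trait] = trial_mod.average_blups(per_env)
        blup_df = pd.DataFrame(blups)
        blup_df.index.name = "line_id"
        blup_df = blup_df.loc[[l for l in blup_df.index if l in pop.dosage.index]]
        blup_df.to_csv(outdir / "blups.csv")
        with open(outdir / "variance_components.json", "w") as fh:
            json.dump(vcs, fh, indent=2)
        manifest["outputs"].update(
            blups="blups.csv", variance_components="variance_components.json"
        )
        record("trial", "ok", t0, traits=traits)
    except ThermoQtlError as exc:
        record("trial", "error", t0, message=str(exc))
        raise

    # -- stage 3: QTL scans ------------------------------------------------
    t0 = time.time()
    q = cfg["qtl"]
    try:
        grid = qtl_mod.dosage_grid(gmap, pop, step=q["step"])
        for trait in traits:
            y = blup_df[trait]
            cof = qtl_mod.select_cofactors(y, grid, k=q["n_cofactors"])
            scan = qtl_mod.CIMScan(y, grid, cof, window=q["window"]).fit()
            scan.threshold = qtl_mod.permutation_threshold(
                y, grid, cof, window=q["window"], n_perm=q["n_perm"],
                alpha=q["alpha"], seed=seeds["qtl"],
            )
            scan.table.to_csv(outdir / f"scan_{trait}.csv", index=False)
            scan.peaks().to_csv(outdir / f"qtl_calls_{trait}.csv", index=False)
            with open(outdir / f"threshold_{trait}.json", "w") as fh:
                json.dump(
                    {"trait": trait, "lod_star": scan.threshold.lod_star,
                     "alpha": q["alpha"], "n_perm": q["n_perm"]}, fh, indent=2,
                )
            manifest["outputs"][f"scan_{trait}"] = f"scan_{trait}.csv"
        record("qtl", "ok", t0)
    except ThermoQtlError as exc:
        record("qtl", "error", t0, message=str(exc))
        raise

    # -- stage 4: genomic prediction ---------------------------------------
    t0 = time.time()
    try:
        X = pop.dosage.loc[blup_df.index]
        gebv = {}
        accuracy = {}
        for trait in traits:
            fit = gs_mod.RidgeBLUP(blup_df[trait], X).fit()
            gebv[trait] = fit.gebv()
            fit.marker_effects.rename("effect").to_csv(
                outdir / f"marker_effects_{trait}.csv", header=True, index_label="marker"
            )
            if cfg["gs"]["loo"]:
                rep = gs_mod.loo_cv(blup_df[trait], X)
                accuracy[trait] = {"r_g": rep.r_g, "p": rep.p_value, "n": rep.n}
        gebv_df = pd.DataFrame(gebv)
        gebv_df.index.name = "line_id"
        gebv_df.to_csv(outdir / "gebv.csv")
        if accuracy:
            with open(outdir / "accuracy.json", "w") as fh:
                json.dump(accuracy, fh, indent=2)
        manifest["outputs"]["gebv"] = "gebv.csv"
        record("gs", "ok", t0)
    except ThermoQtlError as exc:
        record("gs", "error", t0, message=str(exc))
        raise

    # -- stage 5: selection -------------------------------------------------
    t0 = time.time()
    sel = cfg["select"]
    try:
        report = sel_mod.build_selection_report(
            blup_df, gebv_df, n_pheno=sel["n_pheno"], n_gs=sel["n_gs"],
            n_random=sel["n_random"], seed=seeds["select"],
        )
        report.index.name = "line_id"
        report.to_csv(outdir / "selection_report.csv")
        gains = []
        for trait in traits:
            base = float(blup_df[trait].mean())
            for group in ("Pheno", "GS", "Pheno+GS", "Random"):
                ids = report.index[report["group"] == group]
                if len(ids) == 0:
                    continue
                g = sel_mod.gain_under_selection(
                    blup_df.loc[ids, trait], base, trait=trait, group=group
                )
                gains.append(vars(g))
        pd.DataFrame(gains).to_csv(outdir / "gains.csv", index=False)
        manifest["outputs"].update(
            selection_report="selection_report.csv", gains="gains.csv"
        )
        record("select", "ok", t0, groups=report["group"].value_counts().to_dict())
    except ThermoQtlError as exc:
        record("select", "error", t0, message=str(exc))
        raise


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------
def validate_io(
    map_path=None, genotypes_path=None, phenotypes_path=None, image_paths=()
) -> list[dict]:
    """Machine-readable issue list for a set of input files (empty = ok)."""
    issues: list[dict] = []

    def issue(file, problem, **loc):
        issues.append({"file": str(file), "problem": problem, **loc})

    gmap = None
    if map_path is not None:
        try:
            gmap = GeneticMap.from_csv(map_path)
        except (ThermoQtlError, OSError, ValueError) as exc:
            issue(map_path, f"map: {exc}")
    if genotypes_path is not None:
        try:
            df = pd.read_csv(genotypes_path, index_col=0)
            vals = df.to_numpy(dtype=float)
            bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 0.5, 1.0)))
            for r, c in np.argwhere(bad):
                issue(
                    genotypes_path,
                    f"dosage value {vals[r, c]} outside {{0, 0.5, 1}}",
                    row=str(df.index[r]), column=str(df.columns[c]),
                )
            if gmap is not None and list(df.columns) != list(gmap.markers):
                issue(genotypes_path, "genotype columns do not match the map markers")
        except (OSError, ValueError) as exc:
            issue(genotypes_path, f"genotypes: {exc}")
    if phenotypes_path is not None:
        try:
            df = pd.read_csv(phenotypes_path)
            for col in ("line_id", "row", "column"):
                if col not in df.columns:
                    issue(phenotypes_path, f"missing required column {col!r}")
        except (OSError, ValueError) as exc:
            issue(phenotypes_path, f"phenotypes: {exc}")
    for p in image_paths:
        try:
            from .thermal import read_radiometric

            read_radiometric(p)
        except (ThermoQtlError, OSError, ValueError) as exc:
            issue(p, f"image: {exc}")
    return issues
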