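"""End-to-end orchestration of the analysis stages.

Stages run in the order the analysis demands -- simulate (or load), qc,
scan, gdm, offset, egi -- persisting every intermediate artifact under the
output directory and writing a manifest with input hashes, parameters,
per-stage record counts and the final weight.  All randomness flows from
one root seed through named substreams, so identical config + seed gives
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from . import egi as egi_mod
from . import gdm as gdm_mod
from . import gea, synthio, variant_qc, vulnerability

__all__ = ["ConfigError", "DependencyError", "PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "scan", "gdm", "offset", "egi")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DependencyError(RuntimeError):
    """A stage's required input artifact is absent."""


_TOP_KEYS = {"seed", "outdir", "stages", "synthetic", "inputs",
             "qc", "scan", "gdm", "egi"}
_SECTION_KEYS = {
    "qc": {"maf", "miss", "window"},
    "scan": {"models", "k", "alpha", "runs", "null_stride", "bf_threshold",
             "candidate_rule"},
    "gdm": {"r_threshold", "n_reference", "geo_rank_cut", "min_n", "use_geo"},
    "egi": {"population", "iterations", "limit", "normalize_on"},
    "inputs": {"vcf", "sites", "grid", "individuals"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat, human-editable key tree)."""

    seed: int = 0
    outdir: Path = Path("egiscape_out")
    stages: tuple = STAGES
    synthetic: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    gdm: dict = field(default_factory=dict)
    egi: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' or 'inputs' must be given")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if self.inputs is not None and "simulate" in self.stages:
            raise ConfigError("'simulate' stage conflicts with file inputs")
        for section in ("qc", "scan", "gdm", "egi", "inputs"):
            vals = getattr(self, section)
            if vals is None:
                continue
            bad = set(vals) - _SECTION_KEYS[section]
            if bad:
                raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        for frac_key, dom in (("maf", (0, 0.5)), ("miss", (0, 1))):
            v = self.qc.get(frac_key)
            if v is not None and not (dom[0] <= v <= dom[1]):
                raise ConfigError(f"qc.{frac_key} outside {dom}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        bad = set(raw) - _TOP_KEYS
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs {path.name}, produced by stage '{producer}' "
            "which has not run"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return (and persist) the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": {}}
    t0 = time.time()

    paths = {
        "vcf": out / "genotypes.vcf",
        "sites": out / "sites.csv",
        "grid": out / "grid.csv",
        "individuals": out / "individuals.csv",
        "truth": out / "truth.json",
        "filtered": out / "filtered.vcf",
        "assoc": out / "assoc.tsv",
        "consensus": out / "consensus.json",
        "gdmfit": out / "gdmfit.json",
        "rgb": out / "transformed_rgb.csv",
        "vuln": out / "vuln.csv",
        "egi": out / "egi.csv",
        "abc": out / "abc.json",
    }
    if config.inputs is not None:
        for k in ("vcf", "sites", "grid"):
            if k in config.inputs:
                paths[k] = Path(config.inputs[k])
        if "individuals" in config.inputs:
            paths["individuals"] = Path(config.inputs["individuals"])

    if "simulate" in config.stages:
        scfg = synthio.SyntheticConfig(**(config.synthetic or {}),
                                       seed=int(substream(config.seed, "synthio")
                                                .generate_state(1)[0] % (2 ** 31)))
        gm, sites, grid, truth = synthio.generate_landscape(scfg)
        grid = synthio.generate_ei_surfaces(grid, scfg)
        synthio.write_vcf(gm, paths["vcf"])
        synthio.write_sites_csv(sites, paths["sites"])
        synthio.write_grid_csv(grid, paths["grid"])
        gm.individual_table.to_csv(paths["individuals"], index=False)
        synthio.write_truth_json(truth, paths["truth"])
        manifest["stages"]["simulate"] = {
            "individuals": gm.n_individuals, "loci": gm.n_loci,
            "sites": len(sites), "grid_cells": len(grid),
            "adaptive_loci": len(truth.adaptive_locus_ids),
        }
        log.info("simulate: %s", manifest["stages"]["simulate"])

    if "qc" in config.stages:
        _need(paths["vcf"], "qc", "simulate")
        gm = variant_qc.load_genotypes(paths["vcf"])
        gm = variant_qc.attach_sites(gm, _need(paths["individuals"], "qc", "simulate"))
        p = config.qc
        gm = variant_qc.qc_filter(gm, maf_min=p.get("maf", 0.05),
                                  miss_max=p.get("miss", 0.10))
        report = getattr(gm, "filter_report", {})
        gm = variant_qc.window_thin(gm, window_bp=p.get("window", 25))
        synthio.write_vcf(gm, paths["filtered"])
        manifest["stages"]["qc"] = {**report, "after_thinning": gm.n_loci}
        log.info("qc: %s", manifest["stages"]["qc"])

    if "scan" in config.stages:
        _need(paths["filtered"], "scan", "qc")
        gm = variant_qc.load_genotypes(paths["filtered"])
        gm = variant_qc.attach_sites(gm, _need(paths["individuals"], "scan", "simulate"))
        sites = pd.read_csv(_need(paths["sites"], "scan", "simulate"))
        p = config.scan
        seed_scan = int(substream(config.seed, "scan").generate_state(1)[0] % (2 ** 31))
        k = p.get("k", 3)
        rec_log = gea.logistic_scan(gm, sites, alpha=p.get("alpha", 0.01))
        rec_lat = gea.latent_scan(gm, sites, k=k, runs=p.get("runs", 5),
                                  seed=seed_scan)
        rec_bay = gea.bayes_scan(gm, sites, null_stride=p.get("null_stride", 200),
                                 runs=p.get("runs", 5),
                                 bf_threshold=p.get("bf_threshold", 1.5),
                                 seed=seed_scan)
        records = gea.combine_records(rec_log, rec_lat, rec_bay)
        records.to_csv(paths["assoc"], sep="\t", index=False)
        cons = gea.consensus_sets(records)
        paths["consensus"].write_text(json.dumps({
            "union": sorted(cons.union_set),
            "core": sorted(cons.core_set),
            "per_model": {m: sorted(s) for m, s in cons.per_model.items()},
        }, indent=2))
        manifest["stages"]["scan"] = {
            "records": len(records),
            "union": len(cons.union_set), "core": len(cons.core_set),
            **{f"model_{m}": len(s) for m, s in cons.per_model.items()},
        }
        log.info("scan: %s", manifest["stages"]["scan"])

    if "gdm" in config.stages:
        _need(paths["consensus"], "gdm", "scan")
        _need(paths["filtered"], "gdm", "qc")
        gm = variant_qc.load_genotypes(paths["filtered"])
        gm = variant_qc.attach_sites(gm, paths["individuals"])
        sites = pd.read_csv(paths["sites"])
        grid = pd.read_csv(_need(paths["grid"], "gdm", "simulate"))
        cons = json.loads(paths["consensus"].read_text())
        p = config.gdm
        rule = config.scan.get("candidate_rule", "union")
        candidates = cons["core"] if rule == "core" else cons["union"]
        predictors = gdm_mod.prune_predictors(sites,
                                              r_threshold=p.get("r_threshold", 0.8))
        seed_gdm = int(substream(config.seed, "gdm").generate_state(1)[0] % (2 ** 31))
        if candidates:
            retained, ref_fit = gdm_mod.screen_candidates(
                gm, candidates, list(gm.locus_ids), sites, predictors,
                n_reference=p.get("n_reference", 200), seed=seed_gdm,
                min_n=p.get("min_n", 5), geo_rank_cut=p.get("geo_rank_cut", 3))
        else:
            retained, ref_fit = set(), None
        loci_for_fit = sorted(retained) or sorted(candidates) or list(gm.locus_ids)
        d = gdm_mod.pairwise_fst(gm, loci=loci_for_fit, min_n=p.get("min_n", 5))
        fit = gdm_mod.fit_gdm(d, sites, predictors, use_geo=p.get("use_geo", True))
        payload = fit.to_dict()
        payload["retained_loci"] = sorted(retained)
        payload["importance"] = gdm_mod.rank_importance(fit).to_dict(orient="records")
        if ref_fit is not None:
            payload["reference_explained_deviance"] = ref_fit.explained_deviance
        paths["gdmfit"].write_text(json.dumps(payload, indent=2))
        rgb = gdm_mod.transform_pca_rgb(fit, grid)
        rgb.to_csv(paths["rgb"], index=False)
        manifest["stages"]["gdm"] = {
            "candidates": len(candidates), "screened": len(retained),
            "fit_loci": len(loci_for_fit),
            "explained_deviance_pct": round(fit.explained_deviance, 4),
            "predictors": len(predictors),
        }
        log.info("gdm: %s", manifest["stages"]["gdm"])

    if "offset" in config.stages:
        _need(paths["gdmfit"], "offset", "gdm")
        grid = pd.read_csv(_need(paths["grid"], "offset", "simulate"))
        fit = gdm_mod.GDMFit.from_dict(json.loads(paths["gdmfit"].read_text()))
        vuln = vulnerability.build_vulnerability(
            fit, grid, normalize_on=config.egi.get("normalize_on", "masked"))
        vuln.to_csv(paths["vuln"], index=False)
        manifest["stages"]["offset"] = {
            "cells": len(vuln),
            "masked_cells": int(vuln["mask_decreasing"].sum()),
        }
        log.info("offset: %s", manifest["stages"]["offset"])

    if "egi" in config.stages:
        _need(paths["vuln"], "egi", "offset")
        vuln = pd.read_csv(paths["vuln"])
        sel = vuln["mask_decreasing"].to_numpy(dtype=bool)
        if not sel.any():
            raise DependencyError("no declining-suitability cells; EGI undefined")
        problem = egi_mod.EGIProblem(
            dei=vuln.loc[sel, "dei_i"].to_numpy(),
            go=vuln.loc[sel, "go_i"].to_numpy(),
            cell_ids=vuln.loc[sel, "cell_id"].tolist(),
        )
        p = config.egi
        abc_cfg = egi_mod.ABCConfig(
            population=p.get("population", 20),
            iterations=p.get("iterations", 30),
            limit=p.get("limit", 5),
            seed=int(substream(config.seed, "abc").generate_state(1)[0] % (2 ** 31)),
        )
        sol = egi_mod.abc_minimize(problem, abc_cfg)
        egi_mod.egi_map(problem, sol.alpha).to_csv(paths["egi"], index=False)
        paths["abc"].write_text(json.dumps({
            "alpha": sol.alpha, "Y_min": sol.Y_min,
            "trace": sol.trace.tolist(), "degenerate": sol.degenerate,
        }, indent=2))
        manifest["stages"]["egi"] = {
            "cells": problem.n, "alpha": round(sol.alpha, 6),
            "Y_min": round(sol.Y_min, 6), "degenerate": sol.degenerate,
        }
        log.info("egi: %s", manifest["stages"]["egi"])

    manifest["parameters"] = {
        "qc": config.qc, "scan": config.scan, "gdm": config.gdm, "egi": config.egi,
        "synthetic": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in (config.synthetic or {}).items()},
    }
    manifest["inputs"] = {
        name: _sha256(paths[name])
        for name in ("vcf", "sites", "grid") if paths[name].exists()
    }
    log.info("pipeline finished in %.1fs", time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
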