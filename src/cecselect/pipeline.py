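"""End-to-end orchestration: simulate -> preprocess -> screen -> fit ->
assess -> select -> report, with a run manifest tying every output to its
stage, parameters and input digests."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as cio
from .crossval import cross_validate, vip_significance
from .datamodel import TEMPERATURE_RESPONSE
from .errors import ConfigurationError
from .pls import fit_pls, choose_components
from .preprocess import (aggregate_max_by_site, build_response_block,
                         drop_undetected, impute_missing, median_normalize)
from .report import site_difference_table, top_ten_table
from .screen import anova_screen
from .selection import select_contaminants
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("cecselect")

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "folds": 7,
    "components": "auto",
    "imputation": "minimum",
    "force_keep_temperature": True,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunManifest:
    def __init__(self, config: dict, seed: int):
        self.config = config
        self.seed = seed
        self.stages: list[dict] = []

    def record(self, stage: str, params: dict, inputs: list[Path],
               outputs: list[Path]) -> None:
        self.stages.append({
            "stage": stage,
            "params": params,
            "inputs": {str(p): _digest(Path(p)) for p in inputs},
            "outputs": {str(p): _digest(Path(p)) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def to_dict(self) -> dict:
        return {"config": self.config, "seed": self.seed, "stages": self.stages}


def run_all(config: dict, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the full pipeline from a config mapping.

    The config either names input files (``panel``, ``temperatures``,
    ``metabolites``) or contains a ``simulate`` block of
    :class:`SimulationConfig` overrides.  All artifacts plus
    ``manifest.json`` are written under ``out_dir``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, seed)

    has_files = "panel" in cfg and "metabolites" in cfg
    if not has_files and "simulate" not in cfg:
        raise ConfigurationError(
            "config must name input files (panel, metabolites) or a simulate block")

    # stage 1: obtain the study ------------------------------------------
    if has_files:
        panel = cio.read_contaminant_table(cfg["panel"],
                                           temperature_path=cfg.get("temperatures"))
        matrix = cio.read_metabolite_matrix(cfg["metabolites"])
        inputs = [Path(cfg["panel"]), Path(cfg["metabolites"])]
        manifest.record("load", {"panel": str(cfg["panel"])}, inputs, [])
        truth = None
    else:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs["seed"] = int(sim_kwargs.get("seed", seed))
        sim_cfg = SimulationConfig(**sim_kwargs)
        panel, matrix, truth = simulate_study(sim_cfg)
        panel_path, temp_path = out / "panel.csv", out / "temperatures.csv"
        met_path, truth_path = out / "metabolites.csv", out / "truth.json"
        cio.write_contaminant_table(panel, panel_path, temperature_path=temp_path)
        cio.write_metabolite_matrix(matrix, met_path)
        cio.write_json(truth.to_dict(), truth_path)
        manifest.record("simulate", dataclasses.asdict(sim_cfg), [],
                        [panel_path, temp_path, met_path, truth_path])
    log.info("study: %d records, %d samples x %d metabolites",
             len(panel.records), *matrix.values.shape)

    # stage 2: preprocess -------------------------------------------------
    agg = aggregate_max_by_site(panel)
    filt = drop_undetected(agg)
    norm = median_normalize(matrix)
    imp = impute_missing(norm, cfg["imputation"])
    yblock = build_response_block(filt.aggregate, imp.matrix)
    if not cfg["force_keep_temperature"]:
        yblock.force_keep = ()
    agg_path = out / "aggregate.csv"
    filt.aggregate.max_concentration.to_csv(agg_path)
    x_path, y_path = out / "X.csv", out / "Y.csv"
    cio.write_metabolite_matrix(imp.matrix, x_path)
    yblock.values.to_csv(y_path)
    prov_path = out / "provenance.json"
    cio.write_json({
        "dropped_analytes": filt.dropped, "retained_analytes": filt.retained,
        "n_imputed": imp.n_imputed, "imputation": cfg["imputation"],
        "normalization": "median=1, block-wise" if matrix.block_of is not None
                         else "median=1, global",
    }, prov_path)
    manifest.record("preprocess",
                    {"imputation": cfg["imputation"],
                     "n_dropped": len(filt.dropped)},
                    [], [agg_path, x_path, y_path, prov_path])
    log.info("preprocess: %d/%d analytes detected, %d cells imputed",
             len(filt.retained), len(agg.analytes), imp.n_imputed)

    # stage 3: metabolite screen -----------------------------------------
    screen = anova_screen(imp.matrix, alpha=cfg["alpha"])
    screen_path, table1_path = out / "screen.json", out / "site_differences.tsv"
    cio.write_json({
        "alpha": cfg["alpha"], "selected": screen.selected,
        "n_screened": len(screen.table),
        "p": screen.table["p"].to_dict(),
    }, screen_path)
    site_difference_table(screen).to_csv(table1_path, sep="\t", index=False)
    manifest.record("screen", {"alpha": cfg["alpha"],
                               "n_selected": len(screen.selected)},
                    [], [screen_path, table1_path])
    log.info("screen: %d/%d metabolites vary across sites",
             len(screen.selected), len(screen.table))
    if not screen.selected:
        raise ConfigurationError("no metabolite passed the site-variation screen")

    x_df = imp.matrix.values[screen.selected]
    site_arr = imp.matrix.site_of.to_numpy()

    # stage 4: global fit -------------------------------------------------
    if cfg["components"] == "auto":
        a_used = choose_components(x_df, yblock.values, folds=cfg["folds"],
                                   seed=seed, site_of=site_arr)
    else:
        a_used = int(cfg["components"])
    model = fit_pls(x_df, yblock.values, a_used)
    model_path = out / "model.json"
    cio.write_json(model.to_dict(), model_path)
    manifest.record("fit", {"n_components": a_used}, [], [model_path])
    log.info("fit: %d components, R2X %s, R2Y %s", a_used,
             [round(v, 3) for v in model.r2x], [round(v, 3) for v in model.r2y])

    # stage 5: assess -----------------------------------------------------
    cv = cross_validate(x_df, yblock.values, a_used, folds=cfg["folds"],
                        seed=seed, site_of=site_arr)
    vip = vip_significance(x_df, yblock.values, a_used, folds=cfg["folds"],
                           seed=seed, site_of=site_arr)
    cv_path, vip_path = out / "cv.json", out / "vip.json"
    cio.write_json({
        "q2cum": cv.q2cum, "q2y": dict(zip(cv.y_names, cv.q2y.tolist())),
        "folds": cfg["folds"], "n_components": a_used,
    }, cv_path)
    cio.write_json({
        "vip": vip.vip.to_dict(), "se": vip.jackknife_se.to_dict(),
        "p": vip.p.to_dict(),
        "loading_sign": vip.loading_sign.to_dict(),
    }, vip_path)
    manifest.record("assess", {"folds": cfg["folds"]}, [], [cv_path, vip_path])
    log.info("assess: global Q2Cum %.3f", cv.q2cum)

    # stage 6: select -----------------------------------------------------
    trace = select_contaminants(x_df, yblock, alpha=cfg["alpha"],
                                components=cfg["components"],
                                folds=cfg["folds"], seed=seed)
    trace_path, ranked_path = out / "trace.json", out / "ranked.tsv"
    cio.write_json(trace.to_dict(), trace_path)
    trace.ranked.to_csv(ranked_path, sep="\t")
    manifest.record("select", {"alpha": cfg["alpha"],
                               "n_final": len(trace.final["responses"])},
                    [], [trace_path, ranked_path])
    log.info("select: %d responses retained (Q2Cum %.3f vs global %.3f)",
             len(trace.final["responses"]),
             trace.final["q2cum"] if trace.final["q2cum"] is not None else float("nan"),
             trace.global_q2cum)

    # stage 7: report -----------------------------------------------------
    top_path = out / "top_contaminants.tsv"
    top_ten_table(filt.aggregate).to_csv(top_path, sep="\t", index=False)
    manifest.record("report", {}, [], [top_path])

    manifest_path = out / "manifest.json"
    cio.write_json(manifest.to_dict(), manifest_path)
    return manifest
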