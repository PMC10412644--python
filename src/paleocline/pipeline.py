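"""Configuration-driven orchestration of the synthetic end-to-end analyses.

A single YAML config describes which stages to run and their thresholds;
``run`` executes the requested stages in dependency order on
synthetic bundles with known truth, writes per-stage TSV/JSON outputs,
and records a manifest with the seed, every threshold and every
exclusion, sufficient to re-derive each filtering decision. Outputs are
byte-reproducible under a fixed seed (no timestamps in result files).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import (cline_regression, diversity_continuity, fstats, geodist,
               kinship, synthetic_data)
from .genotype_store import write_eigenstrat, write_meta

log = logging.getLogger("paleocline")

#: Full config schema with defaults; unknown keys are rejected.
CONFIG_SCHEMA: dict[str, Any] = {
    "seed": 0,
    "block": {"size_morgans": 0.05, "fallback_bp": 5_000_000},
    "cline": {
        "enabled": True, "k_demes": 20, "n_sites": 20_000, "n_per_deme": 2,
        "min_sites": 5000, "distance": "min", "cooks_factor": 4.0,
        "source_drift": 0.1, "deme_spacing": 1.0, "vrma": 5.0,
    },
    "continuity": {
        "enabled": True, "n_pre": 5, "n_post": 5, "n_sites": 50_000,
        "min_sites_f3": 500,
    },
    "anchor": {"enabled": True, "n_steps": 8, "n_sites": 50_000},
    "cnd": {"enabled": True, "min_depth": 0.1},
    "kinship": {
        "enabled": True, "n_unrelated": 10, "n_sites": 20_000,
        "planted": ["parent-offspring", "identical"],
        "window_mb": 1, "min_depth": 0.1,
    },
}


class ConfigError(ValueError):
    pass


def _merge_config(schema: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in schema.items():
        if isinstance(default, dict):
            out[key] = _merge_config(default, user.get(key, {}) or {},
                                     f"{path}{key}.")
        else:
            out[key] = user.get(key, default)
    unknown = set(user) - set(schema)
    if unknown:
        raise ConfigError(f"unknown config keys: "
                          f"{sorted(path + k for k in unknown)}")
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Load and schema-validate a YAML run config; None gives defaults."""
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        user = {**user, **overrides}
    return _merge_config(CONFIG_SCHEMA, user)


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    bsz = config["block"]["size_morgans"]
    fb = config["block"]["fallback_bp"]
    manifest: dict[str, Any] = {"seed": seed, "config": config, "stages": {},
                                "exclusions": {}}

    if config["cline"]["enabled"]:
        log.info("stage cline: simulate + f4 + least-cost distances + OLS")
        manifest["stages"]["cline"] = _run_cline(config["cline"], seed,
                                                 bsz, fb, out, manifest)
    if config["continuity"]["enabled"]:
        log.info("stage continuity: turnover scenario + f3 scan")
        manifest["stages"]["continuity"] = _run_continuity(
            config["continuity"], seed + 101, bsz, fb, out, manifest)
    if config["anchor"]["enabled"]:
        log.info("stage anchor: lineage scenario + conditioned proportions")
        manifest["stages"]["anchor"] = _run_anchor(
            config["anchor"], seed + 202, bsz, fb, out)
    if config["cnd"]["enabled"] and config["continuity"]["enabled"]:
        log.info("stage cnd: pairwise diversity on the turnover bundle")
        manifest["stages"]["cnd"] = _run_cnd(config["cnd"], seed + 303,
                                             bsz, fb, out)
    if config["kinship"]["enabled"]:
        log.info("stage kinship: planted-pair cohort screen")
        manifest["stages"]["kinship"] = _run_kinship(
            config["kinship"], seed + 404, out)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    log.info("pipeline complete: %s", out)
    return manifest


def _run_cline(cfg, seed, bsz, fb, out: Path, manifest) -> dict:
    panel, matrix, meta, freqs, truth = synthetic_data.simulate_cline(
        cfg["k_demes"], cfg["n_sites"], seed,
        source_drift=cfg["source_drift"], n_per_deme=cfg["n_per_deme"],
        deme_spacing=cfg["deme_spacing"])
    write_eigenstrat(panel, matrix, meta, out / "cline")
    write_meta(meta, out / "cline_meta.tsv")
    from .genotype_store import group_frequencies
    blocks = fstats.make_blocks(panel, bsz, fb)
    by_group = dict(zip(meta["id"], meta["group"]))
    # every deme individual is its own unit; sources/outgroup stay pooled
    grouping = {i: (i if i.startswith("deme") else by_group[i])
                for i in matrix.individuals}
    freqs_tab = group_frequencies(matrix, meta, grouping)

    rows = []
    for ind in matrix.individuals:
        if not ind.startswith("deme"):
            continue
        st = fstats.f4(freqs_tab, "Outgroup", ind, "SourceQ", "SourceP",
                       blocks)
        rows.append({"id": ind, "response": st.estimate, "se": st.se,
                     "n_sites": st.n_snps})
    fstat_tab = pd.DataFrame(rows)
    _write_df(fstat_tab, out / "cline_f4.tsv")

    # least-cost distances over a flat corridor containing the deme map
    k = cfg["k_demes"]
    coords = truth.params["coords"]
    spacing = cfg["deme_spacing"]
    nrows = int(max(y for _, y in coords.values()) / spacing) + 2
    water = geodist.Raster(np.zeros((nrows, k)), cellsize=spacing)
    cost = geodist.reclassify_water(water)
    whg_cell, ag3_cell = (0, 0), (0, k - 1)
    dests = []
    for ind in fstat_tab["id"]:
        x, y = coords[ind.rsplit("_", 1)[0]]
        dests.append((ind, int(y / spacing), int(x / spacing)))
    summary = geodist.multi_source_summary(
        cost, None, {"WHG": [whg_cell], "AG3": [ag3_cell]}, dests,
        vrma_cut=cfg["vrma"], points_are_cells=True)
    _write_df(summary, out / "cline_distances.tsv")
    dist_choice = cfg["distance"]
    whg = summary.loc[summary.source_set == "WHG"].set_index("destination")
    ag3 = summary.loc[summary.source_set == "AG3"].set_index("destination")
    dist_tab = pd.DataFrame({
        "id": fstat_tab["id"],
        "dist_whg": whg.loc[fstat_tab["id"], dist_choice].to_numpy(),
        "dist_ag3": ag3.loc[fstat_tab["id"], dist_choice].to_numpy(),
    })

    obs = cline_regression.assemble_observations(
        fstat_tab, dist_tab, meta, min_sites=cfg["min_sites"],
        distance_choice=dist_choice)
    manifest["exclusions"]["cline"] = {
        r.id: r.exclusion for r in obs.itertuples() if r.exclusion}
    model = cline_regression.fit_cline(obs)
    model = cline_regression.leverage_refit(
        model, obs, cooks_factor=cfg["cooks_factor"])
    report = {
        "coefficients": model.params.round(10).to_dict(),
        "se": model.bse.round(10).to_dict(),
        "pvalues": model.pvalues.round(10).to_dict(),
        "r_squared": round(model.rsquared, 10),
        "n": model.nobs,
        "flagged": model.flagged,
        "refit_coefficients": model.refit.params.round(10).to_dict(),
        "true_alpha_range": [0.0, 1.0],
    }
    (out / "cline_model.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {"n_observations": int(obs["included"].sum()),
            "slope_dist_whg": report["coefficients"]["dist_whg"]}


def _run_continuity(cfg, seed, bsz, fb, out: Path, manifest) -> dict:
    from .genotype_store import group_frequencies
    panel, matrix, meta, truth = synthetic_data.simulate_turnover(
        cfg["n_pre"], cfg["n_post"], cfg["n_sites"], seed)
    blocks = fstats.make_blocks(panel, bsz, fb)
    grouping = {i: (i if i.startswith(("pre", "post")) else "Outgroup")
                for i in matrix.individuals}
    freqs = group_frequencies(matrix, meta, grouping)
    test_ids = truth.params["pre_ids"] + truth.params["post_ids"]
    ages = dict(zip(meta["id"], meta["cal_bp_mid"]))
    anchor = truth.params["pre_ids"][0]
    scan = fstats.continuity_scan(freqs, test_ids, anchor, "Outgroup",
                                  blocks, ages,
                                  min_sites=cfg["min_sites_f3"])
    _write_df(scan, out / "continuity_scan.tsv")
    manifest["exclusions"]["continuity"] = list(
        scan.loc[scan["excluded"], "id"])
    return {"n_flagged": int(scan["discontinuous"].sum()),
            "n_tested": len(scan)}


def _run_anchor(cfg, seed, bsz, fb, out: Path) -> dict:
    panel, matrix, meta, truth = synthetic_data.simulate_anchor_lineage(
        cfg["n_steps"], cfg["n_sites"], seed)
    blocks = fstats.make_blocks(panel, bsz, fb)
    anchor = truth.params["anchor_id"]
    cond = diversity_continuity.anchor_condition(matrix, anchor, panel)
    test = truth.params["pre_ids"] + truth.params["post_ids"]
    res = diversity_continuity.anchor_proportion(matrix, cond, test, blocks,
                                                 anchor=anchor)
    _write_df(res.table, out / "anchor_proportions.tsv")
    return {"n_conditioned": res.n_conditioned, "n_tested": len(res.table)}


def _run_cnd(cfg, seed, bsz, fb, out: Path) -> dict:
    panel, matrix, meta, truth = synthetic_data.simulate_turnover(
        4, 4, 20_000, seed)
    blocks = fstats.make_blocks(panel, bsz, fb)
    pre = truth.params["pre_ids"]
    meta_pre = meta.loc[meta["id"].isin(pre)].copy()
    meta_pre["group"] = "pre"
    pairs, unpaired = diversity_continuity.build_cnd_pairs(
        meta_pre, "pre", min_depth=cfg["min_depth"])
    table, pooled = diversity_continuity.group_cnd(matrix, pairs, blocks)
    _write_df(table, out / "cnd_pairs.tsv")
    return {"n_pairs": len(pairs), "unpaired": unpaired,
            "pooled_cnd": round(pooled.mismatch_rate, 10)}


def _run_kinship(cfg, seed, out: Path) -> dict:
    rng = np.random.default_rng(seed)
    pop = rng.uniform(0.05, 0.95, cfg["n_sites"])
    panel, matrix, meta, truth = synthetic_data.simulate_kin_cohort(
        pop, cfg["n_unrelated"], cfg["planted"], seed + 1)
    table = kinship.kin_screen(matrix, panel, meta,
                               min_depth=cfg["min_depth"],
                               window_bp=int(cfg["window_mb"] * 1e6))
    _write_df(table, out / "kin_screen.tsv")
    confident = table.loc[table["confident"]
                          & (table["class"] != "unrelated")]
    return {"n_pairs": len(table),
            "confident_kin": [f"{r['id1']}-{r['id2']}:{r['class']}"
                              for _, r in confident.iterrows()]}
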