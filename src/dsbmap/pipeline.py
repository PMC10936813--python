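"""Configuration-driven pipeline tying the stages together.

A run config is a plain nested dict (YAML on disk) with a ``stages`` list
selecting any of ``simulate``, ``call_hotspots``, ``interference``,
``compare``, a root ``seed``, an output directory, and per-stage sections.
Every run writes a JSON-like manifest recording the seed, the config hash
and the parameters used (flagging which were overridden from defaults), so
outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as dio
from .compare import (bin_ratios_50kb, correlate_fc_with_timing,
                      hotspot_correlation, log2_ratio_per_hotspot,
                      prepare_timing_track, smooth_ratio)
from .hotspots import (DEFAULT_CUTOFF_HPM, DEFAULT_HANN_WINDOW,
                       DEFAULT_MERGE_GAP, DEFAULT_MIN_LEN, DEFAULT_MIN_READS,
                       call_hotspots, combine_templates, estimate_background,
                       exclude_region, hotspot_strengths, smooth_fullmap)
from .interference import aggregate_and_compare, interference_per_repeat
from .layout import LayoutConfig, build_layout
from .maps import pool_fullmaps
from .simulate import (DoubleCutAssay, SimParams, SingleCutAssay,
                       breaks_to_assay, breaks_to_fullmap, simulate_population)

log = logging.getLogger("dsbmap")

__all__ = ["run_pipeline", "DEFAULTS"]

DEFAULTS = {
    "hann_window": DEFAULT_HANN_WINDOW,
    "cutoff_hpm": DEFAULT_CUTOFF_HPM,
    "min_len": DEFAULT_MIN_LEN,
    "min_reads": DEFAULT_MIN_READS,
    "merge_gap": DEFAULT_MERGE_GAP,
    "bin_kb": 50,
    "loess_numerator": 80,
    "n_orfs": 47,
    "min_orf_len": 5500,
    "epsilon": 1e-4,
    "null_cutoff_hpm": 0.125,
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_simulate(cfg: dict, seed: int, outdir: Path) -> dict:
    layout_cfg = LayoutConfig(**cfg.get("layout", {}))
    layout = build_layout(layout_cfg, seed=seed)
    params = SimParams(seed=seed, **cfg.get("params", {}))
    pop = simulate_population(layout, params)
    fm = breaks_to_fullmap(pop, params, name=cfg.get("name", "sim"))
    dio.write_fullmap(fm, outdir / "fullmap.tsv")
    assays = []
    for a in cfg.get("assays", []):
        if a.get("kind") == "dc":
            assays.append(DoubleCutAssay(a["id"], a["hotspot1"], a["hotspot2"]))
        else:
            assays.append(SingleCutAssay(a["id"], a["hotspot"],
                                         a.get("side", "left")))
    if assays:
        table = breaks_to_assay(pop, assays, mode=cfg.get("mode", "ideal"),
                                repeat=cfg.get("repeat", "r1"))
        dio.write_cut_frequency_table(table, outdir / "cut_frequencies.tsv")
    return {
        "n_cuts": int(len(pop.cuts)),
        "primed_fraction": {int(k): float(v)
                            for k, v in pop.primed_fraction.items()},
        "outputs": ["fullmap.tsv"] + (["cut_frequencies.tsv"] if assays else []),
    }


def _stage_call_hotspots(cfg: dict, seed: int, outdir: Path) -> dict:
    maps = [dio.read_fullmap(p) for p in cfg["fullmaps"]]
    window = int(cfg.get("hann_window", DEFAULTS["hann_window"]))
    cutoff = float(cfg.get("cutoff_hpm", DEFAULTS["cutoff_hpm"]))
    templates = []
    for m in maps:
        sm = smooth_fullmap(m, window)
        templates.append(call_hotspots(
            sm, m, cutoff=cutoff,
            min_len=int(cfg.get("min_len", DEFAULTS["min_len"])),
            min_reads=float(cfg.get("min_reads", DEFAULTS["min_reads"])),
            merge_gap=int(cfg.get("merge_gap", DEFAULTS["merge_gap"]))))
    template = combine_templates(templates, [m.name for m in maps])
    removed = 0
    if cfg.get("exclude"):
        chrom, s, e = cfg["exclude"]
        template, removed = exclude_region(template, (chrom, int(s), int(e)))
    pooled = pool_fullmaps(maps) if len(maps) > 1 else maps[0]
    background = 0.0
    if cfg.get("orfs"):
        orfs = pd.read_csv(cfg["orfs"], sep="\t")
        background = estimate_background(
            pooled, orfs,
            min_orf_len=int(cfg.get("min_orf_len", DEFAULTS["min_orf_len"])),
            n_orfs=int(cfg.get("n_orfs", DEFAULTS["n_orfs"])))
    table = hotspot_strengths(pooled, template, background)
    dio.write_hotspot_table(table, outdir / "hotspots.tsv")
    dio.export_bed(table, outdir / "hotspots.bed")
    return {"n_hotspots": int(len(table)), "n_excluded": removed,
            "background_hpm_per_bp": background,
            "outputs": ["hotspots.tsv", "hotspots.bed"]}


def _stage_interference(cfg: dict, seed: int, outdir: Path) -> dict:
    table = dio.read_cut_frequency_table(cfg["frequencies"])
    per_rep = interference_per_repeat(
        table, dc_assay=cfg["dc_assay"], single1=cfg["single1"],
        single2=cfg["single2"],
        timepoints=cfg.get("timepoints", [6.0, 8.0]),
        epsilon=float(cfg.get("epsilon", DEFAULTS["epsilon"])),
        dc_copies=int(cfg.get("dc_copies", 1)),
        distal_correction=cfg.get("distal_correction"))
    per_rep.to_csv(outdir / "interference.tsv", sep="\t", index=False)
    result = {"outputs": ["interference.tsv"],
              "mean_interference": float(per_rep.loc[~per_rep["excluded"],
                                                     "interference"].mean()),
              "n_repeats": int((~per_rep["excluded"]).sum()),
              "n_excluded": int(per_rep["excluded"].sum())}
    if cfg.get("compare_frequencies"):
        other = dio.read_cut_frequency_table(cfg["compare_frequencies"])
        other_rep = interference_per_repeat(
            other, dc_assay=cfg["dc_assay"], single1=cfg["single1"],
            single2=cfg["single2"],
            timepoints=cfg.get("timepoints", [6.0, 8.0]),
            epsilon=float(cfg.get("epsilon", DEFAULTS["epsilon"])),
            dc_copies=int(cfg.get("dc_copies", 1)),
            distal_correction=cfg.get("distal_correction"))
        vals_a = [None if e else v for v, e in
                  zip(per_rep["interference"], per_rep["excluded"])]
        vals_b = [None if e else v for v, e in
                  zip(other_rep["interference"], other_rep["excluded"])]
        res_a, _ = aggregate_and_compare(vals_a, vals_b)
        result["t_stat"] = res_a.t_stat
        result["p_value"] = res_a.p_value
    return result


def _stage_compare(cfg: dict, seed: int, outdir: Path) -> dict:
    a = dio.read_hotspot_table(cfg["numerator"])
    b = dio.read_hotspot_table(cfg["denominator"])
    corr = hotspot_correlation(a, b, method=cfg.get("method", "pearson"))
    ratios = log2_ratio_per_hotspot(a, b)
    ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
    smoothed = smooth_ratio(ratios, span=float(cfg.get("span", 0.1)))
    smoothed.to_csv(outdir / "ratios_smoothed.tsv", sep="\t", index=False)
    result = {"correlation": {k: v for k, v in corr.items()},
              "outputs": ["ratios.tsv", "ratios_smoothed.tsv"]}
    if cfg.get("centromeres") and cfg.get("chrom_lengths"):
        cens = {k: int(v) for k, v in cfg["centromeres"].items()}
        lens = {k: int(v) for k, v in cfg["chrom_lengths"].items()}
        bin_size = int(cfg.get("bin_kb", DEFAULTS["bin_kb"])) * 1000
        binned = bin_ratios_50kb(a, b, cens, lens, bin_size=bin_size)
        binned.to_csv(outdir / "binned_ratios.tsv", sep="\t", index=False)
        result["outputs"].append("binned_ratios.tsv")
        if cfg.get("timing_track"):
            track = pd.read_csv(cfg["timing_track"], sep="\t")
            timing = prepare_timing_track(
                track,
                loess_numerator=float(cfg.get("loess_numerator",
                                              DEFAULTS["loess_numerator"])),
                bin_size=bin_size)
            res = correlate_fc_with_timing(binned, timing)
            res["pairs"].to_csv(outdir / "fc_vs_timing.tsv", sep="\t",
                                index=False)
            result["timing_spearman"] = {"r": res["r"], "p": res["p"],
                                         "n": res["n"]}
            result["outputs"].append("fc_vs_timing.tsv")
    return result


_STAGES = {
    "simulate": _stage_simulate,
    "call_hotspots": _stage_call_hotspots,
    "interference": _stage_interference,
    "compare": _stage_compare,
}


def run_pipeline(config: dict) -> dict:
    """Execute the selected stages and write a run manifest.

    Returns the manifest dict (also written to ``<out>/manifest.json``).
    Raises on missing inputs for a selected stage.
    """
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("out", "dsbmap_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "config_hash": _config_hash(config),
                "stages": {}, "defaults": DEFAULTS}
    for stage in stages:
        cfg = config.get(stage, {})
        log.info("running stage %s", stage)
        manifest["stages"][stage] = _STAGES[stage](cfg, seed, outdir)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
    return manifest
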