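"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` executes, for whichever inputs the run configuration
provides: gas-log preprocessing (blank-corrected specific methane curves,
timing statistics, termination day), kinetic model fitting, first-order
hydrolysis fitting, Buswell stoichiometry with biodegradability, Van
Krevelen DOM classification, and methane-to-electricity economics.  Stages
with missing inputs are skipped with a logged notice; a stage failure is
isolated and recorded rather than aborting the rest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dom_classify, economics, gas_preprocess, io, kinetics, stoichiometry

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("output_dir", "biomethane_out")
    cfg.setdefault("t_fractions", [0.5, 0.9, 0.95])
    cfg.setdefault("seed", 0)
    return cfg


def _stage_bmp(cfg: dict, outputs: dict, out_dir: Path) -> None:
    inputs = cfg.get("inputs", {})
    if "gas_logs" not in inputs or "channel_meta" not in inputs:
        logger.info("bmp stage skipped: no gas-log inputs configured")
        outputs["bmp"] = {"status": "skipped"}
        return
    logs = io.read_gas_log(inputs["gas_logs"], cfg.get("gas_columns"))
    metas = io.read_channel_meta(inputs["channel_meta"])
    by_id = {m.channel_id: m for m in metas}
    channels = {cid: df for cid, df in logs.groupby("channel_id")}

    blanks = [m for m in metas if m.is_blank]
    if not blanks:
        raise ValueError("no blank channels in metadata; cannot blank-correct")
    blank_curve = gas_preprocess.blank_curve_per_g_inoculum(
        [channels[m.channel_id] for m in blanks], blanks
    )

    curves, labels, rows = [], [], []
    for m in metas:
        if m.is_blank:
            continue
        curve = gas_preprocess.specific_methane_curve(channels[m.channel_id], m, blank_curve)
        curves.append(curve)
        labels.append(m.group_label)
        prod = gas_preprocess.daily_and_hourly_production(curve)
        end = gas_preprocess.detect_termination(prod["daily"]["production"].to_numpy())
        stats = gas_preprocess.timing_stats(curve, cfg["t_fractions"], end_day=end)
        rows.append(
            {"channel_id": m.channel_id, "group": m.group_label,
             "final_ml_per_g_vs": curve.final, "t50": stats.t50, "t90": stats.t90,
             "t95": stats.t95, "end_day": end, "flagged": curve.flagged}
        )
    mean_table = gas_preprocess.group_mean_curves(curves, labels)
    io.write_table(mean_table, out_dir / "specific_curves.csv")
    timing = pd.DataFrame(rows)
    io.write_table(timing, out_dir / "timing_stats.csv")
    outputs["bmp"] = {
        "status": "ok",
        "curves": curves,
        "labels": labels,
        "mean_table": mean_table,
        "timing": timing,
        "files": ["specific_curves.csv", "timing_stats.csv"],
    }


def _stage_kinetics(cfg: dict, outputs: dict, out_dir: Path) -> None:
    bmp = outputs.get("bmp", {})
    if bmp.get("status") != "ok":
        logger.info("kinetics stage skipped: no preprocessed curves")
        outputs["kinetics"] = {"status": "skipped"}
        return
    tables = []
    models = cfg.get("models", list(kinetics.MODEL_NAMES))
    mean_table = bmp["mean_table"]
    for group, sub in mean_table.groupby("group"):
        curve = gas_preprocess.YieldCurve(sub["time_days"].to_numpy(), sub["mean"].to_numpy())
        tab = kinetics.fit_all_models(curve, models=models)
        tab.insert(0, "group", group)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    io.write_table(table, out_dir / "kinetics_table.csv")
    outputs["kinetics"] = {"status": "ok", "table": table, "files": ["kinetics_table.csv"]}


def _stage_hydrolysis(cfg: dict, outputs: dict, out_dir: Path) -> None:
    inputs = cfg.get("inputs", {})
    if "substrate_series" not in inputs:
        logger.info("hydrolysis stage skipped: no substrate series configured")
        outputs["hydrolysis"] = {"status": "skipped"}
        return
    df = io.read_substrate_series(inputs["substrate_series"])
    fit = kinetics.fit_hydrolysis(df["time_days"], df["concentration_g_l"])
    table = pd.DataFrame([{"s0": fit.s0, "k_deg_per_d": fit.k_deg, "r_squared": fit.r_squared}])
    io.write_table(table, out_dir / "hydrolysis.csv")
    outputs["hydrolysis"] = {"status": "ok", "fit": fit, "files": ["hydrolysis.csv"]}


def _stage_stoichiometry(cfg: dict, outputs: dict, out_dir: Path) -> None:
    inputs = cfg.get("inputs", {})
    if "characterization" not in inputs:
        logger.info("stoichiometry stage skipped: no characterization table")
        outputs["stoichiometry"] = {"status": "skipped"}
        return
    comps = io.read_characterization(inputs["characterization"])
    emp_by_group = cfg.get("emp", {})
    bmp = outputs.get("bmp", {})
    if bmp.get("status") == "ok" and not emp_by_group:
        emp_by_group = (
            bmp["timing"].groupby("group")["final_ml_per_g_vs"].mean().to_dict()
        )
    rows = []
    for name, comp in comps.items():
        res = stoichiometry.tmp_from_composition(comp)
        row = {"substrate": name, "tmp_ml_per_g_dry": res.tmp,
               "ch4_coeff": res.ch4_coeff, "co2_coeff": res.co2_coeff}
        for group, emp in emp_by_group.items():
            bd = stoichiometry.biodegradability(emp, res.tmp)
            row[f"bd_pct_{group}"] = bd.bd
        rows.append(row)
    table = pd.DataFrame(rows)
    io.write_table(table, out_dir / "stoichiometry.csv")
    outputs["stoichiometry"] = {"status": "ok", "table": table, "files": ["stoichiometry.csv"]}


def _stage_dom(cfg: dict, outputs: dict, out_dir: Path) -> None:
    inputs = cfg.get("inputs", {})
    if "formulas" not in inputs:
        logger.info("dom stage skipped: no formula table configured")
        outputs["dom"] = {"status": "skipped"}
        return
    df = io.read_formula_table(inputs["formulas"])
    weighting = cfg.get("dom_weighting", "intensity")
    rows, scatter = [], []
    sample_col = df["sample_id"] if "sample_id" in df.columns else pd.Series(["all"] * len(df))
    for sample, sub in df.groupby(sample_col):
        formulas = dom_classify.formulas_from_frame(sub, sample_id=str(sample))
        summary = dom_classify.summarize(formulas, weighting=weighting)
        row = {"sample_id": sample, "weighting": weighting}
        row.update({f"class_{k}": v for k, v in summary.class_shares.items()})
        row.update({f"group_{k}": v for k, v in summary.element_group_shares.items()})
        rows.append(row)
        scatter.append(dom_classify.vk_scatter_table(formulas))
    table = pd.DataFrame(rows)
    io.write_table(table, out_dir / "dom_shares.csv")
    io.write_table(pd.concat(scatter, ignore_index=True), out_dir / "vk_scatter.csv")
    outputs["dom"] = {"status": "ok", "table": table,
                      "files": ["dom_shares.csv", "vk_scatter.csv"]}


def _stage_economics(cfg: dict, outputs: dict, out_dir: Path) -> None:
    raw = cfg.get("economics", {}).get("scenarios")
    if not raw:
        logger.info("economics stage skipped: no scenarios configured")
        outputs["economics"] = {"status": "skipped"}
        return
    consts = {k: v for k, v in cfg.get("economics", {}).items() if k != "scenarios"}
    scenarios = [economics.EconomicScenario(**{**consts, **sc}) for sc in raw]
    table = economics.economics_table(scenarios)
    io.write_table(table, out_dir / "economics.csv")
    outputs["economics"] = {"status": "ok", "table": table, "files": ["economics.csv"]}


_STAGES = (
    ("bmp", _stage_bmp),
    ("kinetics", _stage_kinetics),
    ("hydrolysis", _stage_hydrolysis),
    ("stoichiometry", _stage_stoichiometry),
    ("dom", _stage_dom),
    ("economics", _stage_economics),
)


def run_pipeline(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run every configured stage; returns the report bundle.

    The bundle maps stage name to status ('ok' / 'skipped' / 'failed'),
    in-memory results and written file names.  A run manifest with the
    configuration and per-stage provenance is written to the output
    directory.  Deterministic for fixed inputs and seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Any] = {}
    for name, stage in _STAGES:
        try:
            stage(config, outputs, out_dir)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            outputs[name] = {"status": "failed", "error": str(exc)}
    manifest = {
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items() if k != "gas_columns"},
        "stages": {
            name: {"status": res.get("status"), "files": res.get("files", []),
                   **({"error": res["error"]} if "error" in res else {})}
            for name, res in outputs.items()
        },
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest
    if all(res.get("status") == "failed" for n, res in outputs.items() if n != "manifest"):
        raise RuntimeError("every pipeline stage failed")
    return outputs


def _json_default(obj):  # pragma: no cover
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
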