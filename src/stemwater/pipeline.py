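"""End-to-end orchestration: radius series -> TWD/PLW_E -> loss curves ->
safety areas -> segmented daily-cycle models -> PV curves -> expression.

All randomness (bootstraps, simulation) flows from one root seed through
named substreams, so a fixed (config, seed) yields a byte-identical
``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

import stemwater
from stemwater.config import SimulationConfig, default_config
from stemwater.dendro import (
    RadiusSeries,
    compute_twd,
    cycles_to_frame,
    daily_extremes,
    drought_cycles,
)
from stemwater.expression import delta_delta_ct, expression_psi_model
from stemwater.plcurves import (
    fit_pl_curve,
    per_tree_threshold_anova,
    prepare_plg_inputs,
)
from stemwater.pv import fit_pv_curve, transform_pv_points
from stemwater.safety import classify_sequence, dsa_esa, stomatal_safety_margin
from stemwater.segmented import compare_initial_slopes, fit_segmented
from stemwater.simulate import SyntheticDataset, simulate_experiment

__all__ = ["run_pipeline"]

_CHANNELS = ("PLG", "PLC", "PLWE")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _fit_channel_curves(
    pairs: pd.DataFrame, channel: str, n_boot: int, seed: int
) -> tuple[dict, dict]:
    """Pooled per-species fits and per-tree fits for one channel."""
    pooled: dict[str, Any] = {}
    per_tree: dict[str, tuple[str, Any]] = {}
    for sp, g in pairs.groupby("species"):
        try:
            pooled[str(sp)] = fit_pl_curve(
                g, n_boot=n_boot, seed=seed, channel=channel, species=str(sp)
            )
        except (ValueError, RuntimeError) as e:
            warnings.warn(f"{channel}/{sp}: pooled fit failed ({e})")
    for (sp, tid), g in pairs.groupby(["species", "tree_id"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = fit_pl_curve(
                    g, n_boot=0, seed=seed, channel=channel, species=str(sp)
                )
            per_tree[str(tid)] = (str(sp), curve)
        except (ValueError, RuntimeError):
            continue
    return pooled, per_tree


def run_pipeline(
    config: SimulationConfig | None = None,
    input_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    simulate: bool = True,
    final_campaigns: int = 2,
) -> dict:
    """Run every stage and return (and optionally write) the report.

    Either pass ``input_dir`` holding the five input CSVs plus
    truth.json, or let the pipeline simulate its inputs from ``config``
    (defaulting to the 4-species x 6-tree, 90-day experiment).
    """
    if input_dir is not None:
        data = SyntheticDataset.read(input_dir)
        cfg_json = json.dumps(data.truth.get("config", {}), sort_keys=True)
    elif simulate:
        config = config or default_config(seed=seed)
        config.seed = seed
        data = simulate_experiment(config)
        cfg_json = config.canonical_json()
    else:
        raise ValueError("either input_dir or simulate=True is required")

    report: dict[str, Any] = {
        "provenance": {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": seed,
            "n_boot": n_boot,
            "version": stemwater.__version__,
        },
        "stages": {},
        "species": {},
    }

    # ---- dendrometer stage -------------------------------------------------
    twd_frames, cycle_frames = [], []
    twd_md_rows, twd_info = [], {}
    for tid, g in data.radius_table.groupby("tree_id"):
        series = RadiusSeries.from_frame(g)
        tw = compute_twd(series)
        twd_frames.append(tw.to_frame())
        cycles = daily_extremes(tw)
        dc = drought_cycles(cycles, series)
        twd_info[tid] = {"species": series.species, "twd_max": tw.twd_max}
        if dc:
            cdf = cycles_to_frame(dc, tree_id=str(tid))
            cdf.insert(1, "species", series.species)
            cdf["plwe_pd"] = 100.0 * cdf["twd_pd"] / tw.twd_max
            cycle_frames.append(cdf)
        md = cycles_to_frame(cycles, tree_id=str(tid))
        md.insert(1, "species", series.species)
        md["twd_max"] = tw.twd_max
        twd_md_rows.append(md)
    twd_table = pd.concat(twd_frames, ignore_index=True)
    all_cycles = pd.concat(twd_md_rows, ignore_index=True)
    drought_table = (
        pd.concat(cycle_frames, ignore_index=True) if cycle_frames else pd.DataFrame()
    )
    report["stages"]["dendro"] = {
        "n_trees": int(data.radius_table["tree_id"].nunique()),
        "n_radius_rows": int(len(data.radius_table)),
        "n_drought_cycle_days": int(len(drought_table)),
    }

    # ---- paired observations per channel -----------------------------------
    plg_pairs = prepare_plg_inputs(data.psi_gs_table, final_campaigns=final_campaigns)

    vc = data.vc_table.copy()
    vc["rel"] = (vc["kh"] / vc["kmax"]).clip(0.0, 1.0)
    plc_pairs = vc.rename(columns={"psi_mpa": "psi"})[
        ["tree_id", "species", "psi", "rel"]
    ]

    md_psi = data.psi_gs_table[["date", "tree_id", "species", "psi_mpa"]].copy()
    cyc = all_cycles.copy()
    cyc["date"] = pd.to_datetime(cyc["date"]).dt.date.astype(str)
    plwe_pairs = md_psi.merge(
        cyc[["tree_id", "date", "twd_md", "twd_max"]], on=["tree_id", "date"]
    )
    plwe_pairs["rel"] = (1.0 - plwe_pairs["twd_md"] / plwe_pairs["twd_max"]).clip(0, 1)
    plwe_pairs = plwe_pairs.rename(columns={"psi_mpa": "psi"})

    channel_pairs = {"PLG": plg_pairs, "PLC": plc_pairs, "PLWE": plwe_pairs}
    pooled_curves: dict[str, dict] = {}
    threshold_stats: dict[str, Any] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ch, pairs in channel_pairs.items():
            pooled, per_tree = _fit_channel_curves(pairs, ch, n_boot, seed)
            pooled_curves[ch] = pooled
            try:
                stats = per_tree_threshold_anova(per_tree, x=50.0)
                threshold_stats[ch] = {
                    "anova_f": stats["anova_f"],
                    "anova_p": stats["anova_p"],
                    "tukey": stats["tukey"],
                }
            except ValueError as e:
                threshold_stats[ch] = {"error": str(e)}
    report["stages"]["pl_curves"] = {
        ch: {
            sp: {
                "b": cv.b, "c": cv.c, "n": cv.n_obs,
                "px": cv.px_table,
            }
            for sp, cv in pooled.items()
        }
        for ch, pooled in pooled_curves.items()
    }
    report["stages"]["threshold_anova"] = threshold_stats

    # ---- safety areas and sequence per species -----------------------------
    species_names = sorted(data.radius_table["species"].unique())
    for sp in species_names:
        block: dict[str, Any] = {}
        curves = {ch: pooled_curves[ch].get(sp) for ch in _CHANNELS}
        if all(curves.values()):
            sa = dsa_esa(curves["PLG"], curves["PLWE"], curves["PLC"])
            margin, extrap = stomatal_safety_margin(curves["PLG"], curves["PLC"])
            seq = classify_sequence(
                {ch: curves[ch].px_table[50] for ch in _CHANNELS}
            )
            block["safety"] = {
                "dsa": sa.dsa, "esa": sa.esa, "ratio": sa.ratio,
                "psi_stop": sa.psi_stop, "grid_n": sa.grid_n,
            }
            block["stomatal_safety_margin_mpa"] = margin
            block["margin_extrapolated"] = extrap
            block["sequence"] = seq
            block["thresholds"] = {
                ch: curves[ch].px_table for ch in _CHANNELS
            }
        else:
            block["safety"] = None
        report["species"][sp] = block

    # ---- segmented daily-cycle models --------------------------------------
    seg_block: dict[str, Any] = {}
    if len(drought_table):
        for resp, pred in (
            ("swelling_norm", "plwe_pd"),
            ("shrinkage_norm", "plwe_pd"),
            ("swelling_norm", "shrinkage_norm"),
        ):
            d = drought_table.dropna(subset=[resp, pred])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits = fit_segmented(d, response=resp, predictor=pred)
                    contrasts = compare_initial_slopes(fits)
                seg_block[f"{resp}_vs_{pred}"] = {
                    "fits": {
                        sp: {
                            "breakpoint": f.breakpoint,
                            "slope1": f.slope1, "slope2": f.slope2,
                            "se1": f.se1, "se2": f.se2,
                            "path": f.path, "n": f.n,
                            "degenerate": f.degenerate,
                        }
                        for sp, f in fits.items()
                    },
                    "slope_contrasts": contrasts,
                }
            except (ValueError, RuntimeError) as e:
                seg_block[f"{resp}_vs_{pred}"] = {"error": str(e)}
    report["stages"]["segmented"] = seg_block

    # ---- pressure-volume curves --------------------------------------------
    pv_rows = []
    for leaf_id, leaf in data.pv_table.groupby("leaf_id"):
        dw = float(leaf["dry_weight_g"].iloc[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                transformed, sw = transform_pv_points(leaf, dw)
                res = fit_pv_curve(transformed, sw, dw)
            pv_rows.append(
                {
                    "leaf_id": leaf_id,
                    "tree_id": leaf["tree_id"].iloc[0] if "tree_id" in leaf else "",
                    "species": leaf["species"].iloc[0] if "species" in leaf else "",
                    "period": leaf["period"].iloc[0] if "period" in leaf else "",
                    "psi_tlp": res.psi_tlp,
                    "pi100": res.pi100,
                    "sw": res.sw,
                    "r2_linear": res.r2_linear,
                    "n_linear": res.n_linear,
                }
            )
        except ValueError as e:
            warnings.warn(f"PV leaf {leaf_id}: {e}")
    pv_table = pd.DataFrame(pv_rows)
    pv_block: dict[str, Any] = {"per_leaf_n": int(len(pv_table))}
    if len(pv_table) and {"species", "period"} <= set(pv_table.columns):
        summary = (
            pv_table.groupby(["species", "period"])[["psi_tlp", "pi100"]]
            .mean()
            .reset_index()
        )
        pv_block["summary"] = summary
        if pv_table["period"].nunique() > 1 and pv_table["species"].nunique() > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for var in ("psi_tlp", "pi100"):
                    fit = smf.ols(
                        f"{var} ~ C(species) * C(period)", data=pv_table
                    ).fit()
                    anova = sm.stats.anova_lm(fit, typ=2)
                    pv_block[f"{var}_anova_p"] = {
                        str(k): float(v) for k, v in anova["PR(>F)"].dropna().items()
                    }
    report["stages"]["pv"] = pv_block

    # ---- aquaporin expression ----------------------------------------------
    expr_block: dict[str, Any] = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = delta_delta_ct(data.ct_table)
            model = expression_psi_model(records)
        expr_block = {
            "terms": model["terms"],
            "dropped": model["dropped"],
            "psi_retained": model["psi_retained"],
            "path": model["path"],
            "species_slopes": model["species_slopes"],
            "slope_contrasts": model["slope_contrasts"],
            "n": model["n"],
        }
    except (ValueError, RuntimeError) as e:
        expr_block = {"error": str(e)}
        records = pd.DataFrame()
    report["stages"]["expression"] = expr_block

    report = _jsonable(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        twd_table.to_csv(out / "twd.csv", index=False, float_format="%.6f")
        if len(drought_table):
            drought_table.to_csv(out / "cycles.csv", index=False, float_format="%.6f")
        if len(pv_table):
            pv_table.to_csv(out / "pv_results.csv", index=False, float_format="%.6f")
        if len(records):
            records.to_csv(out / "expression.csv", index=False, float_format="%.6f")
        _write_curve_tables(out, pooled_curves)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, allow_nan=True)
        )
    return report


def _write_curve_tables(out: Path, pooled_curves: dict[str, dict]) -> None:
    curve_rows, thr_rows = [], []
    for ch, pooled in pooled_curves.items():
        for sp, cv in pooled.items():
            curve_rows.append((ch, sp, cv.b, cv.c, cv.n_obs))
            for x, entry in cv.px_table.items():
                thr_rows.append(
                    (ch, sp, x, entry["estimate"], entry["ci_low"],
                     entry["ci_high"], entry["extrapolated"])
                )
    pd.DataFrame(
        curve_rows, columns=["channel", "species", "b", "c", "n"]
    ).to_csv(out / "curves.csv", index=False, float_format="%.6f")
    pd.DataFrame(
        thr_rows,
        columns=["channel", "species", "X", "estimate", "ci_low", "ci_high",
                 "extrapolated_flag"],
    ).to_csv(out / "thresholds.csv", index=False, float_format="%.6f")
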