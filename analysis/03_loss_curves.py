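"""Fit Weibull percentage-loss curves per species and channel.

PLG from baseline-corrected stomatal conductance, PLC from hydraulic
conductivity, PLW_E from midday tree water deficit paired with midday
stem water potential; pooled by species with 1000 case-resampling
bootstrap replicates for threshold CIs, plus per-tree 50% thresholds
compared by ANOVA / Tukey.

Reads results/data and results/twd.csv (from 02); writes
results/curves.csv, results/thresholds.csv, results/threshold_anova.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from stemwater.pipeline import _fit_channel_curves, _write_curve_tables
from stemwater.plcurves import per_tree_threshold_anova, prepare_plg_inputs

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_BOOT = 1000


def channel_pairs() -> dict[str, pd.DataFrame]:
    psi_gs = pd.read_csv(ROOT / "data" / "psi_gs_table.csv")
    vc = pd.read_csv(ROOT / "data" / "vc_table.csv")
    twd = pd.read_csv(ROOT / "twd.csv")
    radius = pd.read_csv(ROOT / "data" / "radius_table.csv",
                         usecols=["tree_id", "species"]).drop_duplicates()

    plg = prepare_plg_inputs(psi_gs)

    vc["rel"] = (vc["kh"] / vc["kmax"]).clip(0, 1)
    plc = vc.rename(columns={"psi_mpa": "psi"})

    # midday TWD per date, normalized by the tree's global maximum
    twd["date"] = pd.to_datetime(twd["timestamp"]).dt.date.astype(str)
    twd["hour"] = pd.to_datetime(twd["timestamp"]).dt.hour
    md = (
        twd[(twd["hour"] >= 12) & (twd["hour"] < 18)]
        .groupby(["tree_id", "date"])["twd_um"].max().rename("twd_md").reset_index()
    )
    md["twd_max"] = md["tree_id"].map(twd.groupby("tree_id")["twd_um"].max())
    plwe = psi_gs.merge(md, on=["tree_id", "date"]).merge(radius_species(radius))
    plwe["rel"] = (1.0 - plwe["twd_md"] / plwe["twd_max"]).clip(0, 1)
    plwe = plwe.rename(columns={"psi_mpa": "psi"})
    return {"PLG": plg, "PLC": plc, "PLWE": plwe}


def radius_species(radius: pd.DataFrame) -> pd.DataFrame:
    return radius[["tree_id", "species"]]


def main() -> None:
    pooled_all, anova_rows = {}, []
    for ch, pairs in channel_pairs().items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled, per_tree = _fit_channel_curves(pairs, ch, N_BOOT, SEED)
            stats = per_tree_threshold_anova(per_tree, x=50.0)
        pooled_all[ch] = pooled
        anova_rows.append((ch, stats["anova_f"], stats["anova_p"]))
        print(f"{ch}: P50 (-MPa) " + ", ".join(
            f"{sp} {cv.px(50):.2f}" for sp, cv in sorted(pooled.items())
        ) + f"; species ANOVA p = {stats['anova_p']:.2e}")
    _write_curve_tables(ROOT, pooled_all)
    pd.DataFrame(anova_rows, columns=["channel", "anova_f", "anova_p"]).to_csv(
        ROOT / "threshold_anova.csv", index=False, float_format="%.6g"
    )


if __name__ == "__main__":
    main()
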