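"""Safety areas, stomatal safety margins and the drought-response
sequence per species.

DSA integrates PLG - PLW_E and ESA integrates PLG - PLC down to the
first 88% threshold; their ratio indexes whether a species prioritizes
tissue hydration (ratio > 1) or vascular integrity (< 1).  The sequence
label orders the three 50% thresholds, merging channels whose bootstrap
CIs overlap.

Reads results/curves.csv and results/thresholds.csv (from 03); writes
results/safety.csv.
"""

from pathlib import Path

import pandas as pd

from stemwater.plcurves import WeibullCurve
from stemwater.safety import classify_sequence, dsa_esa, stomatal_safety_margin

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_curves() -> dict[str, dict[str, WeibullCurve]]:
    curves = pd.read_csv(ROOT / "curves.csv")
    out: dict[str, dict[str, WeibullCurve]] = {}
    for _, row in curves.iterrows():
        out.setdefault(row["channel"], {})[row["species"]] = WeibullCurve(
            channel=row["channel"], species=row["species"],
            b=row["b"], c=row["c"], n_obs=int(row["n"]),
        )
    return out


def main() -> None:
    curves = load_curves()
    thresholds = pd.read_csv(ROOT / "thresholds.csv")
    rows = []
    for sp in sorted(curves["PLG"]):
        plg, plwe, plc = (curves[ch][sp] for ch in ("PLG", "PLWE", "PLC"))
        sa = dsa_esa(plg, plwe, plc)
        margin, extrap = stomatal_safety_margin(plg, plc)
        thr50 = {}
        for ch in ("PLG", "PLC", "PLWE"):
            t = thresholds.query("channel == @ch and species == @sp and X == 50").iloc[0]
            thr50[ch] = {"estimate": t["estimate"],
                         "ci_low": None if pd.isna(t["ci_low"]) else t["ci_low"],
                         "ci_high": None if pd.isna(t["ci_high"]) else t["ci_high"]}
        seq = classify_sequence(thr50)
        rows.append((sp, sa.dsa, sa.esa, sa.ratio, sa.psi_stop, margin, extrap, seq))
        print(f"{sp:8s} DSA/ESA = {sa.ratio:5.2f}  margin = {margin:6.2f} MPa"
              f"{' (extrapolated)' if extrap else ''}  sequence: {seq}")
    pd.DataFrame(
        rows,
        columns=["species", "dsa", "esa", "ratio", "psi_stop",
                 "stomatal_safety_margin_mpa", "margin_extrapolated", "sequence"],
    ).to_csv(ROOT / "safety.csv", index=False, float_format="%.6f")


if __name__ == "__main__":
    main()
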