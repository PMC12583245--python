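"""Pressure-volume analysis: turgor loss point and osmotic potential at
full turgor per leaf, summarized by species and sampling period.

A drop in both parameters from the control to the drought period
indicates osmotic adjustment.  A two-way linear model tests species,
period and their interaction.

Reads results/data/pv_table.csv; writes results/pv_results.csv.
"""

import warnings
from pathlib import Path

import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from stemwater.pv import fit_pv_curve, transform_pv_points

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "data" / "pv_table.csv")
    rows = []
    for leaf_id, leaf in table.groupby("leaf_id"):
        dw = float(leaf["dry_weight_g"].iloc[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                transformed, sw = transform_pv_points(leaf, dw)
                res = fit_pv_curve(transformed, sw, dw)
        except ValueError as e:
            print(f"  skipped {leaf_id}: {e}")
            continue
        rows.append((leaf_id, leaf["species"].iloc[0], leaf["period"].iloc[0],
                     res.psi_tlp, res.pi100, res.sw, res.r2_linear, res.n_linear))
    out = pd.DataFrame(
        rows, columns=["leaf_id", "species", "period", "psi_tlp", "pi100",
                       "sw", "r2_linear", "n_linear"]
    )
    out.to_csv(ROOT / "pv_results.csv", index=False, float_format="%.6f")
    print(out.groupby(["species", "period"])[["psi_tlp", "pi100"]].mean().round(2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for var in ("psi_tlp", "pi100"):
            anova = sm.stats.anova_lm(
                smf.ols(f"{var} ~ C(species) * C(period)", data=out).fit(), typ=2
            )
            p = anova["PR(>F)"]
            print(f"{var}: species p={p['C(species)']:.2e} "
                  f"period p={p['C(period)']:.2e} "
                  f"interaction p={p['C(species):C(period)']:.2e}")


if __name__ == "__main__":
    main()
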