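"""Aquaporin expression versus stem water potential.

ddCt fold changes of PIP1/PIP2 against two housekeeping genes, then a
linear model of fold change against stem water potential with species
and gene effects and backward selection; per-species slopes are
contrasted with Tukey adjustment.

Reads results/data/ct_table.csv; writes results/expression.csv and
results/expression_model.txt.
"""

import warnings
from pathlib import Path

from stemwater.expression import delta_delta_ct, expression_psi_model

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ct = pd.read_csv(ROOT / "data" / "ct_table.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = delta_delta_ct(ct)
        model = expression_psi_model(records)
    records.to_csv(ROOT / "expression.csv", index=False, float_format="%.6f")
    lines = [
        f"retained terms: {model['terms']}",
        f"dropped terms: {model['dropped']}",
        f"fit path: {model['path']}",
        "per-species fold-change slopes (per MPa):",
    ]
    for sp, s in sorted(model["species_slopes"].items()):
        lines.append(f"  {sp:8s} {s:+.4f}")
    if model["slope_contrasts"] is not None:
        lines.append("Tukey slope contrasts:")
        lines.append(model["slope_contrasts"].to_string(index=False))
    text = "\n".join(lines)
    (ROOT / "expression_model.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
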