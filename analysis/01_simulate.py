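"""Generate the synthetic drought experiment that drives the analysis.

Four species (beech, olive, pine, juniper) x 6 trees, a 15-day
well-watered control period followed by a 75-day drought, stem radius
logged every 10 min, midday water potential and stomatal conductance
campaigns, vulnerability curves, pressure-volume curves and aquaporin
qPCR — all from known ground-truth parameters written to truth.json.

Writes results/data/{radius_table,psi_gs_table,vc_table,pv_table,
ct_table}.csv and truth.json.
"""

from pathlib import Path

from stemwater.config import default_config
from stemwater.simulate import simulate_experiment

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = default_config(seed=SEED)
    ds = simulate_experiment(cfg)
    ds.write(OUT)
    print(f"wrote {len(ds.radius_table):,} radius rows for "
          f"{ds.radius_table['tree_id'].nunique()} trees to {OUT}")
    print(f"campaign tables: psi/gs {len(ds.psi_gs_table)}, "
          f"vc {len(ds.vc_table)}, pv {len(ds.pv_table)}, ct {len(ds.ct_table)} rows")


if __name__ == "__main__":
    main()
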