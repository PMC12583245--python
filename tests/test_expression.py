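"""ddCt quantification, primer efficiency and the expression-psi model."""

import numpy as np
import pandas as pd
import pytest

from stemwater._rng import substream
from stemwater.expression import (
    delta_delta_ct,
    expression_psi_model,
    primer_efficiency,
)
from stemwater.simulate import simulate_expression_table


def _ct_table(samples):
    """samples: list of (tree_id, is_control, target_ct, hk1_ct, hk2_ct)."""
    rows = []
    for tid, ctrl, tgt, hk1, hk2 in samples:
        for gene, ct in (("PIP1", tgt), ("RI18S", hk1), ("ACT", hk2)):
            for rep in (1, 2, 3):
                rows.append((tid, "beech", "2021-07-10", gene, rep, ct, ctrl, -1.0))
    return pd.DataFrame(
        rows,
        columns=["tree_id", "species", "date", "gene", "rep", "ct",
                 "is_control", "psi_mpa"],
    )


class TestDeltaDeltaCt:
    def test_worked_arithmetic_example(self):
        # target 24.0, HK means 20 and 22 -> dCt = 3.0; control dCt = 2.5
        tbl = _ct_table(
            [("ctrl", True, 24.5, 20.0, 24.0), ("s1", False, 24.0, 20.0, 22.0)]
        )
        rec = delta_delta_ct(tbl)
        s1 = rec[rec["tree_id"] == "s1"].iloc[0]
        assert s1["delta_ct"] == pytest.approx(3.0)
        assert s1["delta_delta_ct"] == pytest.approx(0.5)
        assert s1["fold_change"] == pytest.approx(2 ** -0.5)

    def test_replicate_means_used(self):
        tbl = _ct_table([("ctrl", True, 24.0, 20.0, 22.0)])
        tbl.loc[(tbl["gene"] == "PIP1") & (tbl["rep"] == 1), "ct"] = 24.1
        tbl.loc[(tbl["gene"] == "PIP1") & (tbl["rep"] == 2), "ct"] = 23.9
        rec = delta_delta_ct(tbl)
        assert rec["ct_mean"].iloc[0] == pytest.approx(24.0)

    def test_livak_identities(self):
        tbl = _ct_table(
            [("ctrl", True, 24.0, 20.0, 22.0),
             ("up", False, 23.0, 20.0, 22.0),    # ddCt -1 -> FC 2
             ("down", False, 26.0, 20.0, 22.0)]  # ddCt +2 -> FC 0.25
        )
        rec = delta_delta_ct(tbl).set_index("tree_id")
        assert rec.loc["up", "fold_change"] == pytest.approx(2.0)
        assert rec.loc["down", "fold_change"] == pytest.approx(0.25)

    def test_control_mean_fold_change_exactly_one_under_noise(self):
        rng = substream(0, "ctrlnoise")
        samples = [(f"c{i}", True, 24.0 + rng.normal(0, 0.3), 20.0, 22.0)
                   for i in range(8)]
        samples += [(f"d{i}", False, 25.0 + rng.normal(0, 0.3), 20.0, 22.0)
                    for i in range(8)]
        rec = delta_delta_ct(_ct_table(samples))
        ctrl = rec[rec["is_control"]]
        assert ctrl["fold_change"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_global_ct_shift_invariance(self):
        tbl = _ct_table(
            [("ctrl", True, 24.0, 20.0, 22.0), ("s1", False, 26.3, 19.7, 22.4)]
        )
        rec_a = delta_delta_ct(tbl)
        shifted = tbl.copy()
        shifted["ct"] += 5.0
        rec_b = delta_delta_ct(shifted)
        np.testing.assert_allclose(
            rec_a["fold_change"], rec_b["fold_change"], atol=1e-12
        )

    def test_missing_housekeeping_gene_rejected(self):
        tbl = _ct_table([("ctrl", True, 24.0, 20.0, 22.0)])
        tbl = tbl[tbl["gene"] != "ACT"]
        with pytest.raises(ValueError, match="housekeeping"):
            delta_delta_ct(tbl)

    def test_wide_replicate_spread_flagged(self):
        tbl = _ct_table([("ctrl", True, 24.0, 20.0, 22.0)])
        tbl.loc[(tbl["gene"] == "PIP1") & (tbl["rep"] == 1), "ct"] = 25.0
        with pytest.warns(UserWarning, match="spread"):
            rec = delta_delta_ct(tbl)
        assert rec["spread_flag"].iloc[0]


class TestPrimerEfficiency:
    def _ladder(self, slope, top_ng=25.0, n=5):
        ng = top_ng / 2.0 ** np.arange(n)
        ct = 20.0 + slope * np.log10(ng)
        return pd.DataFrame({"input_ng": ng, "ct": ct})

    def test_perfect_twofold_ladder_is_exactly_100(self):
        # doubling per cycle: slope = -1/log10(2) ~ -3.3219
        eff = primer_efficiency(self._ladder(-1.0 / np.log10(2.0)))
        assert eff == pytest.approx(100.0, abs=1e-9)

    def test_slope_minus_3_6_gives_89_6_percent(self):
        eff = primer_efficiency(self._ladder(-3.6))
        assert eff == pytest.approx((10 ** (1 / 3.6) - 1) * 100, abs=1e-9)
        assert eff == pytest.approx(89.6, abs=0.1)

    def test_ladder_independent_of_starting_quantity(self):
        e1 = primer_efficiency(self._ladder(-1.0 / np.log10(2.0), top_ng=25.0))
        e2 = primer_efficiency(self._ladder(-1.0 / np.log10(2.0), top_ng=400.0))
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_inverted_series_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            primer_efficiency(self._ladder(+3.3))

    def test_narrow_series_rejected(self):
        df = pd.DataFrame({"input_ng": [25.0, 20.0, 18.0], "ct": [20.0, 20.3, 20.5]})
        with pytest.raises(ValueError, match="span"):
            primer_efficiency(df)


def _model_records(slope_by_species, n_per_species=30, noise=0.15, seed=0):
    frames = []
    for sp, slope in slope_by_species.items():
        rng = substream(seed, "model", sp)
        n_ctrl = max(4, n_per_species // 5)
        psis = np.concatenate(
            [np.full(n_ctrl, -0.5), np.sort(rng.uniform(-4.5, -1.0, n_per_species - n_ctrl))[::-1]]
        )
        samples = pd.DataFrame(
            {
                "tree_id": [f"{sp}_t{i % 5}" for i in range(len(psis))],
                "species": sp,
                "date": [f"d{i:03d}" for i in range(len(psis))],
                "psi_mpa": psis,
                "is_control": [i < n_ctrl for i in range(len(psis))],
            }
        )
        frames.append(
            simulate_expression_table(
                samples, slope, noise, substream(seed, "tblseed", sp).integers(2**31)
            )
        )
    return delta_delta_ct(pd.concat(frames, ignore_index=True))


class TestPsiModel:
    def test_null_slope_term_usually_removed(self):
        removed = 0
        n_sims = 100
        for i in range(n_sims):
            rec = _model_records({"beech": 0.0}, n_per_species=20, seed=500 + i)
            model = expression_psi_model(rec, try_mixed=False)
            if not model["psi_retained"]:
                removed += 1
        assert removed >= 0.9 * n_sims

    def test_contrasting_slopes_keep_interaction_and_order(self):
        rec = _model_records({"olive": 0.05, "pine": 0.15}, n_per_species=40, seed=3)
        model = expression_psi_model(rec, try_mixed=False)
        assert model["psi_retained"]
        assert "psi:species" in model["terms"]
        assert model["species_slopes"]["olive"] < model["species_slopes"]["pine"]

    def test_collinear_psi_rejected(self):
        rec = _model_records({"beech": 0.1}, seed=1)
        rec["psi_mpa"] = -2.0
        with pytest.raises(ValueError):
            expression_psi_model(rec)
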