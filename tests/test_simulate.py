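"""The synthetic-experiment generator: determinism, trivial identities and
ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from stemwater.config import default_config, species_presets
from stemwater.dendro import RadiusSeries, compute_twd
from stemwater.plcurves import fit_pl_curve, px_from_params
from stemwater.pv import fit_pv_curve, transform_pv_points
from stemwater.simulate import (
    psi_schedule_series,
    pv_closed_form,
    simulate_experiment,
    simulate_expression_table,
    simulate_pv_points,
    simulate_radius_series,
    simulate_vc_samples,
)
from tests.conftest import make_noiseless_config


def _flat_psi(value, days=5, freq="10min"):
    t = pd.date_range("2021-07-01", periods=days * 144, freq=freq)
    return pd.Series(np.full(len(t), value), index=t)


class TestExperiment:
    def test_same_config_same_seed_identical_tables(self, small_config):
        a = simulate_experiment(small_config)
        b = simulate_experiment(small_config)
        for name in ("radius_table", "psi_gs_table", "vc_table", "pv_table", "ct_table"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert a.truth == b.truth

    def test_different_seed_differs(self, small_config):
        import copy

        a = simulate_experiment(small_config)
        cfg2 = copy.deepcopy(small_config)
        cfg2.seed = small_config.seed + 1
        b = simulate_experiment(cfg2)
        assert not np.allclose(
            a.radius_table["radius_um"], b.radius_table["radius_um"]
        )

    def test_radius_row_count_is_product_of_design(self):
        cfg = default_config(seed=0)
        assert cfg.n_trees_per_species == 6 and len(cfg.species_params) == 4
        ds = simulate_experiment(cfg)
        per_day = 24 * 60 // cfg.sampling.radius_interval_min
        assert len(ds.radius_table) == 4 * 6 * cfg.sampling.campaign_days * per_day

    def test_daily_mean_psi_declines_monotonically(self):
        cfg = default_config(seed=0)
        t = pd.date_range("2021-07-01", periods=90 * 144, freq="10min")
        psi = psi_schedule_series(cfg.psi_schedule, t)
        daily = psi.groupby(psi.index.normalize()).mean()
        assert np.all(np.diff(daily.to_numpy()) < 0)

    def test_truth_round_trips_through_json(self, small_config, tmp_path):
        import json

        ds = simulate_experiment(small_config)
        blob = json.dumps(ds.truth, sort_keys=True)
        assert json.loads(blob) == ds.truth
        ds.write(tmp_path)
        from stemwater.simulate import SyntheticDataset

        back = SyntheticDataset.read(tmp_path)
        assert back.truth == ds.truth
        assert len(back.radius_table) == len(ds.radius_table)

    def test_child_tables_reference_known_trees(self, small_config):
        ds = simulate_experiment(small_config)
        known = set(ds.radius_table["tree_id"])
        for name in ("psi_gs_table", "vc_table", "ct_table"):
            assert set(getattr(ds, name)["tree_id"]) <= known

    def test_invalid_config_names_field(self):
        cfg = default_config(seed=0)
        cfg.species_params["beech"].twd_max_um = -1.0
        with pytest.raises(ValueError, match="twd_max_um"):
            simulate_experiment(cfg)

    def test_noiseless_experiment_recovers_weibull_truth(self):
        """With all noise off and a deep drought, each channel's fit
        returns the generating (b, c) to 1e-4 relative."""
        cfg = make_noiseless_config(species=("beech",))
        sp = cfg.species_params["beech"]
        ds = simulate_experiment(cfg)

        vc = ds.vc_table.rename(columns={"psi_mpa": "psi"}).copy()
        vc["rel"] = vc["kh"] / vc["kmax"]
        cv = fit_pl_curve(vc, n_boot=0, channel="PLC")
        assert cv.b == pytest.approx(sp.b_plc, rel=1e-4)
        assert cv.c == pytest.approx(sp.c_plc, rel=1e-4)

        from stemwater.plcurves import prepare_plg_inputs

        plg = prepare_plg_inputs(ds.psi_gs_table)
        cvg = fit_pl_curve(plg, n_boot=0, channel="PLG")
        assert cvg.b == pytest.approx(sp.b_plg, rel=1e-4)
        assert cvg.c == pytest.approx(sp.c_plg, rel=1e-4)


class TestRadius:
    def test_constant_zero_psi_pure_growth_nondecreasing(self):
        sp = species_presets()["beech"]
        sp.noise_radius_um = 0.0
        sim = simulate_radius_series(_flat_psi(0.0), sp, seed=0)
        assert np.all(np.diff(sim.series.r) >= 0)
        assert np.all(sim.true_twd_um == 0)

    def test_psi_at_weibull_scale_gives_632_percent_depletion(self):
        sp = species_presets()["beech"]
        sp.noise_radius_um = 0.0
        sp.growth_rate_um_day = 0.0
        sim = simulate_radius_series(_flat_psi(-sp.b_plwe), sp, seed=0)
        expected = sp.twd_max_um * (1 - np.exp(-1))
        np.testing.assert_allclose(sim.true_twd_um, expected, rtol=1e-12)
        np.testing.assert_allclose(sim.true_plwe_pct, 100 * (1 - np.exp(-1)))

    def test_compute_twd_round_trips_true_twd_noiselessly(self):
        """Once the series has touched its running maximum (psi ~ 0 at
        night), the prefix-max deficit equals the desorption truth."""
        cfg = make_noiseless_config(species=("pine",), campaign_days=40)
        sp = cfg.species_params["pine"]
        t = pd.date_range("2021-07-01", periods=40 * 144, freq="10min")
        psi = psi_schedule_series(cfg.psi_schedule, t, sp.diurnal_psi_amplitude_mpa)
        sim = simulate_radius_series(psi, sp, seed=0)
        tw = compute_twd(sim.series)
        first_max = np.argmax(psi.to_numpy() == 0.0)
        np.testing.assert_allclose(
            tw.twd[first_max:], sim.true_twd_um[first_max:], atol=1e-9
        )

    def test_irregular_timestamps_rejected(self):
        t = pd.DatetimeIndex(
            ["2021-07-01 00:00", "2021-07-01 00:10", "2021-07-01 00:30"]
        )
        psi = pd.Series([-1.0, -1.0, -1.0], index=t)
        with pytest.raises(ValueError, match="regular"):
            simulate_radius_series(psi, species_presets()["beech"], seed=0)


class TestVcSamples:
    def test_zero_tension_gives_kmax_and_scale_gives_e_inverse(self):
        sp = species_presets()["olive"]
        df = simulate_vc_samples(sp, [0.0, -sp.b_plc], noise_sd=0.0, seed=0)
        assert df["kh"].iloc[0] == pytest.approx(sp.k_max)
        assert df["kh"].iloc[1] / sp.k_max == pytest.approx(np.exp(-1))

    def test_noisy_recovery_of_p50_within_5_percent(self):
        sp = species_presets()["olive"]
        p50 = px_from_params(sp.b_plc, sp.c_plc, 50)
        levels = -np.linspace(0.05, 2 * p50, 30)
        df = simulate_vc_samples(sp, levels, noise_sd=0.03 * sp.k_max, seed=11)
        df = df.rename(columns={"psi_mpa": "psi"})
        df["rel"] = df["kh"] / df["kmax"]
        cv = fit_pl_curve(df, n_boot=0)
        assert cv.px(50) == pytest.approx(p50, rel=0.05)

    def test_positive_psi_and_negative_noise_rejected(self):
        sp = species_presets()["pine"]
        with pytest.raises(ValueError):
            simulate_vc_samples(sp, [0.5], noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_vc_samples(sp, [-1.0], noise_sd=-0.1, seed=0)


class TestPvPoints:
    def test_full_saturation_psi_is_zero_by_construction(self):
        # psi(R=1) = turgor (-pi100) + osmotic (pi100) = 0
        pi100 = -2.0
        assert max(0.0, -pi100) + pi100 == 0.0

    def test_rigid_cell_limit_is_linear_in_water_deficit(self):
        """With a huge elastic modulus, turgor vanishes immediately and
        -1/psi is linear in (1 - RWC) across all points."""
        df = simulate_pv_points(-2.0, 1e9, n_points=10)
        x = 1.0 - (df["fresh_weight_g"] - 0.4) / 0.6
        y = -1.0 / df["psi_mpa"]
        r = np.corrcoef(x, y)[0, 1]
        assert r**2 > 1 - 1e-12

    def test_noiseless_recovery_of_pi100_within_1_percent(self):
        df = simulate_pv_points(-2.0, 10.0, n_points=14)
        transformed, sw = transform_pv_points(df, dw=0.4)
        res = fit_pv_curve(transformed, sw, dw=0.4)
        assert res.pi100 == pytest.approx(-2.0, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            simulate_pv_points(-2.0, 10.0, n_points=5)

    def test_closed_form_turgor_loss_point(self):
        truth = pv_closed_form(-2.0, 10.0)
        assert truth["rwc_tlp"] == pytest.approx(0.8)
        assert truth["psi_tlp_mpa"] == pytest.approx(-2.5)


class TestExpressionTable:
    def _samples(self, psis, controls):
        return pd.DataFrame(
            {
                "tree_id": [f"t{i}" for i in range(len(psis))],
                "date": "2021-07-10",
                "psi_mpa": psis,
                "is_control": controls,
            }
        )

    def test_zero_noise_controls_have_unit_fold_change(self):
        from stemwater.expression import delta_delta_ct

        tbl = simulate_expression_table(
            self._samples([-0.5, -0.5, -3.0], [True, True, False]),
            slope_fc_per_mpa=0.2,
            noise_sd_ct=0.0,
            seed=0,
        )
        rec = delta_delta_ct(tbl)
        ctrl = rec[rec["is_control"]]
        np.testing.assert_allclose(ctrl["fold_change"], 1.0, atol=1e-12)

    def test_needs_two_housekeeping_genes(self):
        with pytest.raises(ValueError, match="housekeeping"):
            simulate_expression_table(
                self._samples([-0.5, -2.0], [True, False]),
                slope_fc_per_mpa=0.2,
                noise_sd_ct=0.0,
                seed=0,
                hk_genes=("RI18S",),
            )

    def test_slope_recovered_within_25_percent(self):
        from stemwater.expression import delta_delta_ct, expression_psi_model

        rng = np.random.default_rng(5)
        psis = np.concatenate([np.full(6, -0.5), rng.uniform(-5, -1, 18)])
        controls = [True] * 6 + [False] * 18
        tbl = simulate_expression_table(
            self._samples(list(psis), controls),
            slope_fc_per_mpa=0.2,
            noise_sd_ct=0.15,
            seed=21,
        )
        tbl["species"] = "beech"
        rec = delta_delta_ct(tbl)
        model = expression_psi_model(rec)
        slope = model["species_slopes"]["beech"]
        assert slope == pytest.approx(0.2, rel=0.25)
        assert slope > 0
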