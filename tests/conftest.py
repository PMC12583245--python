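import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stemwater.config import default_config, species_presets

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_noiseless_config(seed: int = 0, species=("beech",), psi_end=-20.0,
                          n_trees: int = 1, campaign_days: int = 60):
    """A clean-room experiment: no noise, no tree-to-tree variation, no
    growth, near-zero starting tension and a drought deep enough to
    deplete every channel — downstream fits should recover the generating
    parameters almost exactly."""
    presets = {k: v for k, v in species_presets().items() if k in species}
    cfg = default_config(seed=seed)
    cfg.species_params = presets
    cfg.n_trees_per_species = n_trees
    cfg.sampling.campaign_days = campaign_days
    cfg.psi_schedule.psi_start_mpa = -0.01
    cfg.psi_schedule.psi_end_mpa = psi_end
    cfg.psi_schedule.drought_start_day = 10
    cfg.psi_schedule.drought_length_days = campaign_days - 15
    for p in cfg.species_params.values():
        p.noise_radius_um = 0.0
        p.noise_gs = 0.0
        p.noise_kh_frac = 0.0
        p.noise_psi_mpa = 0.0
        p.noise_ct = 0.0
        p.tree_scale_jitter = 0.0
        p.growth_rate_um_day = 0.0
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_config():
    """A reduced noisy experiment for pipeline smoke tests."""
    cfg = default_config(seed=7)
    cfg.species_params = {
        k: v for k, v in species_presets().items() if k in ("beech", "pine")
    }
    cfg.n_trees_per_species = 3
    cfg.sampling.campaign_days = 45
    cfg.psi_schedule.drought_start_day = 8
    cfg.psi_schedule.drought_length_days = 35
    cfg.validate()
    return cfg


@pytest.fixture()
def sine_radius():
    """Two weeks of a pure diurnal radius cycle (no trend), 10-min step."""
    t = pd.date_range("2021-07-01", periods=14 * 144, freq="10min")
    hours = t.hour + t.minute / 60.0
    r = 1000.0 + 5.0 * np.cos(2 * np.pi * (hours - 13.0) / 24.0)
    return t, r
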