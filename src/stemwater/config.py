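"""Simulation configuration: species parameter presets and the drought
schedule used by the synthetic-experiment generator.

The four presets (beech, olive, pine, juniper) encode species-contrasted
Weibull loss curves for stomatal conductance (PLG), stem hydraulic
conductivity (PLC) and stem elastic water (PLW_E).  The 50% thresholds of
the presets follow the published species ranking for a beech / olive /
pine / juniper drought experiment: stomata close first in every species,
embolism precedes elastic dehydration in the angiosperms, the two nearly
coincide in pine, and elastic dehydration precedes embolism in the highly
embolism-resistant juniper.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any


def scale_from_p50(p50: float, c: float) -> float:
    """Weibull scale ``b`` (MPa tension) from a 50% threshold and shape.

    PL(T) = 100 (1 - exp(-(T/b)^c)) reaches 50 at T = b (ln 2)^(1/c).
    """
    if p50 <= 0 or c <= 0:
        raise ValueError("p50 and c must be positive tensions")
    return p50 / math.log(2.0) ** (1.0 / c)


@dataclass
class SpeciesParams:
    """Ground-truth parameters for one species.

    Weibull pairs (b, c) are (scale in MPa tension, dimensionless shape)
    for the three loss channels; ``twd_max_um`` is the stem's maximum
    elastic shrinkage; noise terms are additive Gaussian SDs per channel.
    """

    name: str
    b_plg: float
    c_plg: float
    b_plc: float
    c_plc: float
    b_plwe: float
    c_plwe: float
    twd_max_um: float
    gs_max: float  # mmol m-2 s-1
    k_max: float  # kg m-1 s-1 MPa-1
    growth_rate_um_day: float
    diurnal_psi_amplitude_mpa: float = 0.4
    noise_radius_um: float = 1.5
    noise_gs: float = 6.0
    noise_kh_frac: float = 0.03  # SD as a fraction of k_max
    noise_psi_mpa: float = 0.08
    noise_ct: float = 0.15
    gs_floor_frac: float = 0.08  # residual conductance + porometer bias
    tree_scale_jitter: float = 0.05  # lognormal SD on per-tree Weibull scales
    pi100_control_mpa: float = -1.8
    pi100_drought_mpa: float = -2.4
    epsilon_mpa: float = 12.0  # bulk elastic modulus for PV generation
    pip_slope_per_mpa: float = 0.10  # fold-change decline per MPa of tension

    def validate(self) -> None:
        for f in ("b_plg", "c_plg", "b_plc", "c_plc", "b_plwe", "c_plwe"):
            if getattr(self, f) <= 0:
                raise ValueError(f"species_params.{f} must be > 0")
        if self.twd_max_um <= 0:
            raise ValueError("species_params.twd_max_um must be > 0")
        if self.gs_max <= 0:
            raise ValueError("species_params.gs_max must be > 0")
        if self.k_max <= 0:
            raise ValueError("species_params.k_max must be > 0")
        for f in ("noise_radius_um", "noise_gs", "noise_kh_frac",
                  "noise_psi_mpa", "noise_ct", "tree_scale_jitter"):
            if getattr(self, f) < 0:
                raise ValueError(f"species_params.{f} must be >= 0")
        if self.pi100_control_mpa >= 0 or self.pi100_drought_mpa >= 0:
            raise ValueError("species_params.pi100 must be < 0 MPa")
        if self.epsilon_mpa <= 0:
            raise ValueError("species_params.epsilon_mpa must be > 0")


@dataclass
class PsiSchedule:
    """Drought course of daily-mean stem water potential (MPa, <= 0).

    The daily mean declines logistically in time from ``psi_start`` to
    ``psi_end`` across the drought window; a diurnal sinusoid with midday
    minimum is superimposed per species.
    """

    psi_start_mpa: float = -0.5
    psi_end_mpa: float = -10.0
    drought_start_day: int = 15
    drought_length_days: int = 75
    decline_shape: str = "logistic"

    def validate(self) -> None:
        if not (self.psi_end_mpa < self.psi_start_mpa <= 0):
            raise ValueError("psi_schedule requires psi_end < psi_start <= 0")
        if self.drought_start_day < 0:
            raise ValueError("psi_schedule.drought_start_day must be >= 0")
        if self.drought_length_days <= 0:
            raise ValueError("psi_schedule.drought_length_days must be > 0")
        if self.decline_shape != "logistic":
            raise ValueError("psi_schedule.decline_shape must be 'logistic'")


@dataclass
class Sampling:
    radius_interval_min: int = 10
    campaign_days: int = 90
    start_date: str = "2021-07-01"  # campaign day 0 (control period onset)

    def validate(self) -> None:
        if self.radius_interval_min <= 0 or 1440 % self.radius_interval_min:
            raise ValueError("sampling.radius_interval_min must divide 1440")
        if self.campaign_days < 2:
            raise ValueError("sampling.campaign_days must be >= 2")


@dataclass
class SimulationConfig:
    species_params: dict[str, SpeciesParams] = field(default_factory=dict)
    psi_schedule: PsiSchedule = field(default_factory=PsiSchedule)
    n_trees_per_species: int = 6
    sampling: Sampling = field(default_factory=Sampling)
    growth_stop_psi_mpa: float = -1.0  # growth gates off below this daily mean
    seed: int = 0

    def validate(self) -> None:
        if not self.species_params:
            raise ValueError("species_params must name at least one species")
        for sp in self.species_params.values():
            sp.validate()
        self.psi_schedule.validate()
        self.sampling.validate()
        if self.n_trees_per_species < 1:
            raise ValueError("n_trees_per_species must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        species = {k: SpeciesParams(**v) for k, v in d["species_params"].items()}
        return cls(
            species_params=species,
            psi_schedule=PsiSchedule(**d["psi_schedule"]),
            n_trees_per_species=d["n_trees_per_species"],
            sampling=Sampling(**d["sampling"]),
            growth_stop_psi_mpa=d.get("growth_stop_psi_mpa", -1.0),
            seed=d["seed"],
        )

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _preset(name: str, p50g: float, cg: float, p50c: float, cc: float,
            p50w: float, cw: float, **kw: Any) -> SpeciesParams:
    return SpeciesParams(
        name=name,
        b_plg=scale_from_p50(p50g, cg), c_plg=cg,
        b_plc=scale_from_p50(p50c, cc), c_plc=cc,
        b_plwe=scale_from_p50(p50w, cw), c_plwe=cw,
        **kw,
    )


def species_presets() -> dict[str, SpeciesParams]:
    """Ground-truth presets reproducing the published 50% thresholds
    (tension, -MPa): PLG50 / PLWE50 / PLC50 = beech 1.54/5.66/2.86,
    olive 2.93/8.08/4.75, pine 2.16/3.77/3.88, juniper 2.94/5.95/14.11."""
    return {
        "beech": _preset(
            "beech", 1.54, 3.0, 2.86, 4.0, 5.66, 2.5,
            twd_max_um=420.0, gs_max=250.0, k_max=1.2,
            growth_rate_um_day=8.0,
            pi100_control_mpa=-1.8, pi100_drought_mpa=-2.3,
            pip_slope_per_mpa=0.10,
        ),
        "olive": _preset(
            "olive", 2.93, 3.0, 4.75, 4.0, 8.08, 2.5,
            twd_max_um=300.0, gs_max=180.0, k_max=0.8,
            growth_rate_um_day=5.0,
            pi100_control_mpa=-2.2, pi100_drought_mpa=-2.7,
            pip_slope_per_mpa=0.05,
        ),
        "pine": _preset(
            "pine", 2.16, 3.0, 3.88, 3.0, 3.77, 2.5,
            twd_max_um=500.0, gs_max=150.0, k_max=1.0,
            growth_rate_um_day=6.0,
            pi100_control_mpa=-1.6, pi100_drought_mpa=-2.8,
            pip_slope_per_mpa=0.10,
        ),
        "juniper": _preset(
            "juniper", 2.94, 3.0, 14.11, 1.6, 5.95, 2.5,
            twd_max_um=260.0, gs_max=120.0, k_max=0.6,
            growth_rate_um_day=3.0,
            pi100_control_mpa=-1.7, pi100_drought_mpa=-3.0,
            pip_slope_per_mpa=0.07,
        ),
    }


def default_config(seed: int = 0, **overrides: Any) -> SimulationConfig:
    """The default synthetic experiment: 4 species x 6 trees, 90-day
    campaign at 10-min radius logging, 15-day control then 75-day drought."""
    cfg = SimulationConfig(species_params=species_presets(), seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
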