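"""Synthetic drought-experiment generator with known ground truth.

Emulates a potted-tree dry-down: a control period with daily irrigation,
then irrigation withheld while stem water potential declines monotonically
(daily mean, logistic in time) with a superimposed diurnal cycle.  Stem
radius is growth plus elastic desorption plus noise; stomatal conductance,
hydraulic conductivity and stem elastic water all decline along Weibull
loss curves with species-contrasted parameters; leaf pressure-volume
points follow an osmotic + linear-elastic turgor model; and aquaporin
qPCR Ct values encode a fold change that declines linearly with water
potential.  Every channel is generated from the returned truth, so the
full pipeline can be validated against known parameters.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from stemwater._rng import substream
from stemwater.config import PsiSchedule, SimulationConfig, SpeciesParams
from stemwater.dendro import RadiusSeries

__all__ = [
    "SyntheticDataset",
    "psi_schedule_series",
    "weibull_fraction_lost",
    "simulate_radius_series",
    "simulate_vc_samples",
    "simulate_pv_points",
    "pv_closed_form",
    "simulate_expression_table",
    "simulate_experiment",
]

_FLOAT_FMT = "%.6f"


def weibull_fraction_lost(psi: np.ndarray | float, b: float, c: float) -> np.ndarray:
    """Weibull CDF of tension: fraction of the channel lost at stem ``psi``
    (MPa, <= 0), with scale ``b`` (MPa tension) and shape ``c``."""
    tension = np.abs(np.minimum(np.asarray(psi, dtype=float), 0.0))
    return 1.0 - np.exp(-((tension / b) ** c))


def psi_schedule_series(
    schedule: PsiSchedule,
    times: pd.DatetimeIndex,
    diurnal_amplitude_mpa: float = 0.4,
    gs_curve: tuple[float, float] | None = None,
    residual_amplitude_frac: float = 0.15,
) -> pd.Series:
    """Stem water potential over ``times``: logistic daily-mean decline from
    psi_start to psi_end across the drought window plus a diurnal sinusoid
    with its minimum at 13:00, clipped at 0 MPa.

    The diurnal swing is transpiration-driven, so when ``gs_curve``
    (Weibull b, c of the stomatal loss channel) is given the amplitude is
    scaled by the surviving stomatal conductance at the daily-mean
    potential, decaying to ``residual_amplitude_frac`` of the well-watered
    amplitude once stomata have closed (cuticular/residual water loss).
    """
    schedule.validate()
    t0 = times[0].normalize()
    day = (times - t0) / pd.Timedelta(days=1)
    mid = schedule.drought_start_day + schedule.drought_length_days / 2.0
    tau = schedule.drought_length_days / 10.0
    frac = 1.0 / (1.0 + np.exp(-(day.to_numpy(float) - mid) / tau))
    daily = schedule.psi_start_mpa + (schedule.psi_end_mpa - schedule.psi_start_mpa) * frac
    amp = np.full_like(daily, diurnal_amplitude_mpa)
    if gs_curve is not None:
        b, c = gs_curve
        rel_gs = 1.0 - weibull_fraction_lost(daily, b, c)
        amp = amp * (residual_amplitude_frac + (1.0 - residual_amplitude_frac) * rel_gs)
    hour = times.hour.to_numpy(float) + times.minute.to_numpy(float) / 60.0
    diurnal = -0.5 * amp * np.cos(2.0 * np.pi * (hour - 13.0) / 24.0)
    return pd.Series(np.minimum(daily + diurnal, 0.0), index=times, name="psi_mpa")


def _check_regular(times: pd.DatetimeIndex) -> pd.Timedelta:
    deltas = np.diff(times.asi8)
    if len(deltas) == 0 or not (deltas == deltas[0]).all() or deltas[0] <= 0:
        raise ValueError("psi_series timestamps must be regular and increasing")
    return pd.Timedelta(deltas[0], unit="ns")


@dataclass
class SimulatedRadius:
    """A radius series plus the generating truth."""

    series: RadiusSeries
    true_twd_um: np.ndarray  # twd_max * W(psi), the elastic depletion truth
    true_plwe_pct: np.ndarray  # 100 * W(psi) exactly
    growth_um: np.ndarray


def simulate_radius_series(
    psi_series: pd.Series,
    params: SpeciesParams,
    seed: int,
    tree_id: str = "t1",
    growth_stop_psi_mpa: float = -1.0,
    r0_um: float = 10_000.0,
) -> SimulatedRadius:
    """radius(t) = r0 + growth(t) - twd_max * W(psi(t)) + noise.

    Growth follows a logistic cumulative curve whose increments are gated
    off once the daily-mean water potential falls below
    ``growth_stop_psi_mpa``.  The elastic depletion truth
    twd_max * W(psi) and 100 * W(psi) are returned alongside.
    """
    params.validate()
    times = pd.DatetimeIndex(psi_series.index)
    step = _check_regular(times)
    psi = psi_series.to_numpy(float)

    frac_lost = weibull_fraction_lost(psi, params.b_plwe, params.c_plwe)
    true_twd = params.twd_max_um * frac_lost

    # daily-mean psi, broadcast back to the sub-daily grid
    dates = times.normalize()
    daily_mean = pd.Series(psi, index=times).groupby(dates).transform("mean").to_numpy()

    day = ((times - times[0]) / pd.Timedelta(days=1)).to_numpy(float)
    if params.growth_rate_um_day > 0:
        g_mid = 10.0
        g_tau = 5.0
        total = params.growth_rate_um_day * 4.0 * g_tau  # max slope = rate
        potential = total / (1.0 + np.exp(-(day - g_mid) / g_tau))
        inc = np.diff(potential, prepend=potential[0])
        inc[daily_mean < growth_stop_psi_mpa] = 0.0
        growth = np.cumsum(inc)
    else:
        growth = np.zeros_like(psi)

    rng = substream(seed, "radius", tree_id)
    noise = rng.normal(0.0, params.noise_radius_um, size=psi.shape) \
        if params.noise_radius_um > 0 else np.zeros_like(psi)
    r = r0_um + growth - true_twd + noise
    series = RadiusSeries(tree_id=tree_id, species=params.name, t=times, r=r)
    return SimulatedRadius(
        series=series,
        true_twd_um=true_twd,
        true_plwe_pct=100.0 * frac_lost,
        growth_um=growth,
    )


def simulate_vc_samples(
    params: SpeciesParams,
    psi_levels: Sequence[float],
    noise_sd: float,
    seed: int,
    n_trees: int = 1,
    tree_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vulnerability-curve samples: k_h = k_max exp(-(|psi|/b_plc)^c_plc)
    plus noise, clipped to [0, k_max]."""
    params.validate()
    levels = np.asarray(psi_levels, dtype=float)
    if (levels > 0).any():
        raise ValueError("psi_levels must be <= 0 MPa")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if tree_ids is None:
        tree_ids = [f"t{i + 1}" for i in range(n_trees)]
    rng = substream(seed, "vc", params.name)
    rows = []
    for tid in tree_ids:
        rel = 1.0 - weibull_fraction_lost(levels, params.b_plc, params.c_plc)
        kh = params.k_max * rel
        if noise_sd > 0:
            kh = kh + rng.normal(0.0, noise_sd, size=kh.shape)
        kh = np.clip(kh, 0.0, params.k_max)
        for psi, k in zip(levels, kh):
            rows.append((tid, params.name, psi, k, params.k_max))
    return pd.DataFrame(rows, columns=["tree_id", "species", "psi_mpa", "kh", "kmax"])


def pv_closed_form(pi100: float, epsilon: float) -> dict[str, float]:
    """Turgor-loss point of the generating PV model.

    Turgor pressure max(0, -pi100 - epsilon (1 - R)) vanishes at
    1 - R = |pi100| / epsilon, where psi equals the osmotic term
    pi100 / R."""
    x_tlp = -pi100 / epsilon
    if x_tlp >= 1:
        raise ValueError("epsilon too small: turgor never lost before R=0")
    rwc_tlp = 1.0 - x_tlp
    return {"rwc_tlp": rwc_tlp, "psi_tlp_mpa": pi100 / rwc_tlp}


def simulate_pv_points(
    pi100: float,
    epsilon: float,
    n_points: int = 14,
    noise_sd: float = 0.0,
    seed: int = 0,
    dry_weight_g: float = 0.40,
    saturated_weight_g: float = 1.00,
    leaf_id: str = "leaf1",
) -> pd.DataFrame:
    """Bench-dry pressure-volume sequence.

    psi = psi_p + psi_pi with osmotic psi_pi = pi100 / R and turgor
    psi_p = max(0, -pi100 - epsilon (1 - R)); fresh weight
    dw + R (sw - dw) with relative water content R descending from ~1.
    Requires at least six points (the campaign minimum).
    """
    if pi100 >= 0:
        raise ValueError("pi100 must be < 0 MPa")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 MPa")
    if n_points < 6:
        raise ValueError("n_points must be >= 6")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    # dry well past turgor loss (at 1 - R = |pi100|/epsilon) so at least
    # half the points sit on the osmotic line
    span = min(0.6, 2.0 * (-pi100) / epsilon)
    x = np.linspace(0.01, span, n_points)  # 1 - R
    rs = 1.0 - x
    psi_pi = pi100 / rs
    psi_p = np.maximum(0.0, -pi100 - epsilon * x)
    psi = psi_p + psi_pi
    fw = dry_weight_g + rs * (saturated_weight_g - dry_weight_g)
    if noise_sd > 0:
        rng = substream(seed, "pv", leaf_id)
        psi = np.minimum(psi + rng.normal(0.0, noise_sd, size=psi.shape), -1e-3)
        fw = fw + rng.normal(0.0, noise_sd * 0.01, size=fw.shape)
    return pd.DataFrame(
        {
            "leaf_id": leaf_id,
            "fresh_weight_g": fw,
            "psi_mpa": psi,
            "dry_weight_g": dry_weight_g,
        }
    )


def simulate_expression_table(
    psi_by_sample: pd.DataFrame,
    slope_fc_per_mpa: float,
    noise_sd_ct: float,
    seed: int,
    hk_genes: Sequence[str] = ("RI18S", "ACT"),
    target_genes: Sequence[str] = ("PIP1", "PIP2"),
    n_reps: int = 3,
    hk_base_ct: Sequence[float] = (18.0, 22.0),
    dct_control: float = 3.0,
    fc_floor: float = 0.05,
) -> pd.DataFrame:
    """qPCR Ct table whose implied fold change declines linearly with psi.

    FC(psi) = 1 + slope (psi - mean control psi), clipped at ``fc_floor``;
    Ct_target = mean(housekeeping Ct) + dct_control - log2 FC + noise per
    technical replicate.  ``psi_by_sample`` needs columns tree_id, date,
    psi_mpa, is_control (and optionally species).
    """
    if len(hk_genes) < 2:
        raise ValueError("at least 2 housekeeping genes are required")
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be >= 0")
    samples = psi_by_sample.reset_index(drop=True)
    if not samples["is_control"].any():
        raise ValueError("psi_by_sample must flag control samples")
    psi0 = samples.loc[samples["is_control"], "psi_mpa"].mean()
    rng = substream(seed, "expression")
    hk_mean = float(np.mean(hk_base_ct))
    rows = []
    for _, s in samples.iterrows():
        fc = max(fc_floor, 1.0 + slope_fc_per_mpa * (s["psi_mpa"] - psi0))
        species = s.get("species", "sp")
        for gene, base in zip(hk_genes, hk_base_ct):
            for rep in range(1, n_reps + 1):
                ct = base + (rng.normal(0.0, noise_sd_ct) if noise_sd_ct else 0.0)
                rows.append((s["tree_id"], species, s["date"], gene, rep, ct,
                             bool(s["is_control"]), s["psi_mpa"]))
        for gene in target_genes:
            mu = hk_mean + dct_control - np.log2(fc)
            for rep in range(1, n_reps + 1):
                ct = mu + (rng.normal(0.0, noise_sd_ct) if noise_sd_ct else 0.0)
                rows.append((s["tree_id"], species, s["date"], gene, rep, ct,
                             bool(s["is_control"]), s["psi_mpa"]))
    return pd.DataFrame(
        rows,
        columns=["tree_id", "species", "date", "gene", "rep", "ct",
                 "is_control", "psi_mpa"],
    )


@dataclass
class SyntheticDataset:
    """The five input tables of a synthetic experiment plus its truth."""

    radius_table: pd.DataFrame
    psi_gs_table: pd.DataFrame
    vc_table: pd.DataFrame
    pv_table: pd.DataFrame
    ct_table: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("radius_table", "psi_gs_table", "vc_table", "pv_table", "ct_table"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       float_format=_FLOAT_FMT)
        (out / "truth.json").write_text(json.dumps(self.truth, sort_keys=True, indent=1))

    @classmethod
    def read(cls, in_dir: str | Path) -> "SyntheticDataset":
        p = Path(in_dir)
        tables = {
            name: pd.read_csv(p / f"{name}.csv")
            for name in ("radius_table", "psi_gs_table", "vc_table", "pv_table", "ct_table")
        }
        truth = json.loads((p / "truth.json").read_text())
        return cls(truth=truth, **tables)


def _campaign_days(schedule: PsiSchedule, campaign_days: int) -> list[float]:
    """Midday measurement days: twice weekly in the control period, three
    times weekly during drought."""
    days: list[float] = []
    d = 2.0
    while d < schedule.drought_start_day:
        days.append(d)
        d += 3.5
    d = schedule.drought_start_day + 1.0
    while d < campaign_days - 1:
        days.append(d)
        d += 7.0 / 3.0
    return days


def _jittered(params: SpeciesParams, rng: np.random.Generator) -> SpeciesParams:
    """Per-tree variant of the species truth: lognormal jitter on the
    Weibull scales and on maximum elastic shrinkage."""
    p = dataclasses.replace(params)
    sd = params.tree_scale_jitter
    if sd > 0:
        p.b_plg = params.b_plg * float(np.exp(rng.normal(0.0, sd)))
        p.b_plc = params.b_plc * float(np.exp(rng.normal(0.0, sd)))
        p.b_plwe = params.b_plwe * float(np.exp(rng.normal(0.0, sd)))
        p.twd_max_um = params.twd_max_um * float(np.exp(rng.normal(0.0, sd)))
    return p


def simulate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic experiment from ``config``.

    Deterministic: identical (config, seed) yields identical tables.
    """
    config.validate()
    seed = config.seed
    sch = config.psi_schedule
    samp = config.sampling
    start = pd.Timestamp(samp.start_date)
    times = pd.date_range(
        start,
        start + pd.Timedelta(days=samp.campaign_days) - pd.Timedelta(minutes=samp.radius_interval_min),
        freq=f"{samp.radius_interval_min}min",
    )
    meas_days = _campaign_days(sch, samp.campaign_days)

    radius_rows, gs_rows, vc_frames, pv_frames, ct_frames = [], [], [], [], []
    truth_trees: dict[str, dict] = {}

    for sp_name, sp in config.species_params.items():
        psi = psi_schedule_series(
            sch, times, sp.diurnal_psi_amplitude_mpa, gs_curve=(sp.b_plg, sp.c_plg)
        )
        tree_ids = [f"{sp_name}_t{i + 1}" for i in range(config.n_trees_per_species)]
        for tid in tree_ids:
            rng_tree = substream(seed, "tree", tid)
            p_tree = _jittered(sp, rng_tree)
            truth_trees[tid] = {
                "species": sp_name,
                "b_plg": p_tree.b_plg, "c_plg": p_tree.c_plg,
                "b_plc": p_tree.b_plc, "c_plc": p_tree.c_plc,
                "b_plwe": p_tree.b_plwe, "c_plwe": p_tree.c_plwe,
                "twd_max_um": p_tree.twd_max_um,
            }
            sim = simulate_radius_series(
                psi, p_tree, seed, tree_id=tid,
                growth_stop_psi_mpa=config.growth_stop_psi_mpa,
            )
            radius_rows.append(
                pd.DataFrame(
                    {
                        "timestamp": times,
                        "tree_id": tid,
                        "species": sp_name,
                        "radius_um": sim.series.r,
                    }
                )
            )
            # midday campaigns: paired stem psi and stomatal conductance
            rng_gs = substream(seed, "gs", tid)
            floor = sp.gs_floor_frac * sp.gs_max
            for d in meas_days:
                t_md = start + pd.Timedelta(days=d, hours=13)
                idx = times.get_indexer([t_md], method="nearest")[0]
                psi_true = psi.iloc[idx]
                psi_obs = min(0.0, psi_true + rng_gs.normal(0.0, sp.noise_psi_mpa))
                rel = 1.0 - weibull_fraction_lost(psi_true, p_tree.b_plg, p_tree.c_plg)
                gs = sp.gs_max * rel + floor + rng_gs.normal(0.0, sp.noise_gs)
                gs_rows.append((times[idx].date().isoformat(), tid, sp_name,
                                psi_obs, max(gs, 0.0)))
            # vulnerability curve on the same trees
            t_max = min(1.6 * p_tree.b_plc, 25.0)
            levels = -np.linspace(0.0, t_max, 12)
            vc_frames.append(
                simulate_vc_samples(
                    p_tree, levels, sp.noise_kh_frac * sp.k_max,
                    substream(seed, "vcseed", tid).integers(2**31),
                    tree_ids=[tid],
                )
            )
            # pressure-volume curves, one leaf per period
            for period, pi100 in (("control", sp.pi100_control_mpa),
                                  ("drought", sp.pi100_drought_mpa)):
                rng_pv = substream(seed, "pvjitter", tid, period)
                pi_leaf = pi100 * float(np.exp(rng_pv.normal(0.0, 0.03)))
                leaf = simulate_pv_points(
                    pi_leaf, sp.epsilon_mpa, n_points=12, noise_sd=0.01,
                    seed=rng_pv.integers(2**31), leaf_id=f"{tid}_{period}",
                )
                leaf.insert(1, "tree_id", tid)
                leaf.insert(2, "species", sp_name)
                leaf.insert(3, "period", period)
                pv_frames.append(leaf)
        # qPCR sampling: one control date, three drought dates, per tree
        ct_days = [8.0,
                   sch.drought_start_day + 10.0,
                   sch.drought_start_day + 25.0,
                   sch.drought_start_day + 40.0]
        ct_samples = []
        rng_ct = substream(seed, "ctpsi", sp_name)
        for tid in tree_ids:
            for j, d in enumerate(ct_days):
                t_md = start + pd.Timedelta(days=d, hours=13)
                idx = times.get_indexer([t_md], method="nearest")[0]
                psi_obs = min(0.0, psi.iloc[idx] + rng_ct.normal(0.0, sp.noise_psi_mpa))
                ct_samples.append((tid, sp_name, times[idx].date().isoformat(),
                                   psi_obs, j == 0))
        samples = pd.DataFrame(
            ct_samples, columns=["tree_id", "species", "date", "psi_mpa", "is_control"]
        )
        ct_frames.append(
            simulate_expression_table(
                samples, sp.pip_slope_per_mpa, sp.noise_ct,
                substream(seed, "ctseed", sp_name).integers(2**31),
            )
        )

    radius_table = pd.concat(radius_rows, ignore_index=True)
    psi_gs_table = pd.DataFrame(
        gs_rows, columns=["date", "tree_id", "species", "psi_mpa", "gs"]
    )
    dataset = SyntheticDataset(
        radius_table=radius_table,
        psi_gs_table=psi_gs_table,
        vc_table=pd.concat(vc_frames, ignore_index=True),
        pv_table=pd.concat(pv_frames, ignore_index=True),
        ct_table=pd.concat(ct_frames, ignore_index=True),
        truth={
            "config": config.to_dict(),
            "trees": truth_trees,
            "pv_closed_form": {
                sp: {
                    period: pv_closed_form(getattr(p, f"pi100_{period}_mpa"), p.epsilon_mpa)
                    for period in ("control", "drought")
                }
                for sp, p in config.species_params.items()
            },
        },
    )
    _check_child_trees(dataset)
    return dataset


def _check_child_trees(ds: SyntheticDataset) -> None:
    known = set(ds.radius_table["tree_id"])
    for name in ("psi_gs_table", "vc_table", "ct_table"):
        extra = set(getattr(ds, name)["tree_id"]) - known
        if extra:
            warnings.warn(f"{name} contains tree_ids absent from radius_table: {extra}")
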