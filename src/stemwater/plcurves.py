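"""Weibull percentage-loss curves against stem water potential.

All three channels share one model: the surviving fraction of the channel
(stomatal conductance for PLG, hydraulic conductivity for PLC, elastic
water storage for PLW_E) declines with tension T = |psi| as

    rel(T) = exp(-(T/b)^c),      PL(T) = 100 (1 - rel(T))

with scale b (MPa tension, the 63.2% loss point) and shape c.  Thresholds
PX = b (-ln(1 - X/100))^(1/c) give the tension at X% loss.  Confidence
intervals come from case-resampling bootstrap of the paired observations
(pooled across trees by default); PX estimates beyond the sampled tension
range are flagged as extrapolated and their CI bounds reported
unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from stemwater._rng import substream

__all__ = [
    "WeibullCurve",
    "weibull_pl",
    "weibull_rel",
    "px_from_params",
    "prepare_plg_inputs",
    "fit_pl_curve",
    "per_tree_threshold_anova",
    "px_sx_parameterization",
]

DEFAULT_PX_LEVELS = (12, 50, 88, 95)


def weibull_rel(psi, b: float, c: float):
    """Relative (surviving) value at stem ``psi`` (MPa, <= 0)."""
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be > 0")
    psi = np.asarray(psi, dtype=float)
    if (psi > 0).any():
        raise ValueError("psi must be <= 0 MPa (tension sign convention)")
    return np.exp(-((np.abs(psi) / b) ** c))


def weibull_pl(psi, b: float, c: float):
    """Percentage loss at stem ``psi``: 100 (1 - exp(-(|psi|/b)^c))."""
    return 100.0 * (1.0 - weibull_rel(psi, b, c))


def px_from_params(b: float, c: float, x: float) -> float:
    """Tension (-MPa, positive) at which X% of the channel is lost."""
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    return b * (-np.log(1.0 - x / 100.0)) ** (1.0 / c)


def px_sx_parameterization(b: float, c: float, x: float = 50.0) -> tuple[float, float]:
    """Read-only conversion to the (PX, SX) parameterization used by
    sigmoidal vulnerability-curve fitters: the X% threshold and the slope
    of relative loss (% per MPa) at that threshold."""
    px = px_from_params(b, c, x)
    v = (x - 100.0) * np.log(1.0 - x / 100.0)
    sx = c / px * v  # d(PL)/dT at T = PX
    return float(px), float(sx)


@dataclass
class WeibullCurve:
    """A fitted percentage-loss curve with bootstrap threshold CIs."""

    channel: str
    b: float
    c: float
    n_obs: int
    species: str = ""
    px_table: dict[int, dict[str, float | None]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0
    tension_max: float = np.inf  # largest sampled tension
    extrapolation_warning: bool = False

    def pl(self, psi):
        return weibull_pl(psi, self.b, self.c)

    def rel(self, psi):
        return weibull_rel(psi, self.b, self.c)

    def px(self, x: float) -> float:
        return px_from_params(self.b, self.c, x)


def prepare_plg_inputs(
    gs_table: pd.DataFrame,
    final_campaigns: int = 2,
) -> pd.DataFrame:
    """Per-tree preprocessing of stomatal-conductance campaigns.

    The minimum g_s over each tree's last ``final_campaigns`` campaign
    dates is subtracted from its whole series (removing residual
    conductance and porometer bias so losses span 0-100%), the corrected
    series is scaled by its maximum, and missing water-potential readings
    are replaced by the previous campaign's value and flagged
    ``carried_forward``.

    ``gs_table`` columns: date, tree_id, species, psi_mpa, gs.
    """
    if final_campaigns < 1:
        raise ValueError("final_campaigns must be >= 1")
    out = []
    for tid, g in gs_table.groupby("tree_id"):
        g = g.sort_values("date").reset_index(drop=True)
        if g["date"].nunique() < 3:
            raise ValueError(f"tree {tid}: needs >= 3 campaigns")
        # carry forward unreliable/missing psi from the previous campaign
        psi = g["psi_mpa"].copy()
        carried = psi.isna()
        psi = psi.ffill()
        if psi.isna().any():
            raise ValueError(f"tree {tid}: first campaign psi missing")
        final_dates = sorted(g["date"].unique())[-final_campaigns:]
        baseline = g.loc[g["date"].isin(final_dates), "gs"].min()
        corrected = g["gs"] - baseline
        gs_max = corrected.max()
        if gs_max <= 0:
            raise ValueError(f"tree {tid}: corrected g_s has no positive maximum")
        rel = (corrected / gs_max).clip(0.0, 1.0)
        out.append(
            pd.DataFrame(
                {
                    "tree_id": tid,
                    "species": g["species"],
                    "date": g["date"],
                    "psi": psi,
                    "value": g["gs"],
                    "rel": rel,
                    "channel": "PLG",
                    "carried_forward": carried,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _fit_weibull_core(
    tension: np.ndarray,
    rel: np.ndarray,
    extra_starts: list[tuple[float, float]] | None = None,
) -> tuple[float, float, float]:
    """Least-squares (b, c) for rel = exp(-(T/b)^c); returns (b, c, sse).

    Starts from a log-linearization of interior points plus a coarse grid
    over b in [0.5, 20] MPa and c in [0.5, 10] to dodge local minima on
    flat curves.
    """
    starts: list[tuple[float, float]] = []
    interior = (rel > 1e-4) & (rel < 1 - 1e-4) & (tension > 0)
    if interior.sum() >= 2:
        y = np.log(-np.log(rel[interior]))
        x = np.log(tension[interior])
        if np.ptp(x) > 0:
            c0, icpt = np.polyfit(x, y, 1)
            if c0 > 0:
                starts.append((float(np.exp(-icpt / c0)), float(c0)))
    starts += extra_starts or [(0.5, 1.0), (2.0, 2.0), (5.0, 4.0), (20.0, 1.0), (10.0, 8.0)]

    def resid(theta):
        b, c = np.exp(theta)
        with np.errstate(over="ignore"):  # exp(-inf) -> 0 is the right limit
            return np.exp(-((tension / b) ** c)) - rel

    best = None
    for b0, c0 in starts:
        b0 = min(max(b0, 1e-3), 1e3)
        c0 = min(max(c0, 1e-2), 50.0)
        try:
            sol = least_squares(resid, np.log([b0, c0]), method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[2] - 1e-15:
            best = (float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), sse)
    if best is None:
        raise RuntimeError("Weibull fit failed to converge from all starts")
    return best


def fit_pl_curve(
    obs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    px_levels: tuple[int, ...] = DEFAULT_PX_LEVELS,
    channel: str = "",
    species: str = "",
    coverage_guard: tuple[float, float] = (0.8, 0.5),
    min_obs: int = 5,
) -> WeibullCurve:
    """Fit a Weibull loss curve to paired (psi, rel) observations.

    ``obs`` needs columns psi (MPa <= 0) and rel (in [0, 1]); any table
    from :func:`prepare_plg_inputs` or built from k_h/k_max or
    1 - TWD/TWD_max qualifies.  Bootstrap CIs are percentile intervals of
    PX over ``n_boot`` case resamples of the observations.  PX estimates
    beyond the sampled tension range carry no CI (reported None) and the
    curve is flagged extrapolated.
    """
    psi = obs["psi"].to_numpy(float)
    # rel is not clipped here: truncating noise around rel ~ 1 or 0 would
    # bias the fit; channel preprocessing decides any clipping
    rel = obs["rel"].to_numpy(float)
    if (psi > 0).any():
        raise ValueError("psi must be <= 0 MPa")
    ok = np.isfinite(psi) & np.isfinite(rel)
    psi, rel = psi[ok], rel[ok]
    if len(psi) < min_obs:
        raise ValueError(f"need at least {min_obs} observations")
    tension = -psi
    warn_flag = False
    hi, lo = coverage_guard
    if rel.max() < hi or rel.min() > lo:
        warnings.warn(
            f"observations span rel [{rel.min():.2f}, {rel.max():.2f}]; "
            "curve may be extrapolated"
        )
        warn_flag = True

    b, c, _ = _fit_weibull_core(tension, rel)
    t_max = float(tension.max())

    boot_px = {x: [] for x in px_levels}
    if n_boot > 0:
        rng = substream(seed, "bootstrap", channel, species)
        n = len(tension)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                bb, cb, _ = _fit_weibull_core(
                    tension[idx], rel[idx], extra_starts=[(b, c)]
                )
            except RuntimeError:
                continue
            for x in px_levels:
                boot_px[x].append(px_from_params(bb, cb, x))

    px_table: dict[int, dict[str, float | None]] = {}
    for x in px_levels:
        est = px_from_params(b, c, x)
        extrapolated = est > t_max
        lo_ci = hi_ci = None
        if boot_px[x] and not extrapolated:
            # outward order statistics: with few hundred replicates the
            # interpolated percentile narrows the interval and undercovers
            lo_ci = float(np.percentile(boot_px[x], 2.5, method="lower"))
            hi_ci = float(np.percentile(boot_px[x], 97.5, method="higher"))
        px_table[int(x)] = {
            "estimate": float(est),
            "ci_low": lo_ci,
            "ci_high": hi_ci,
            "extrapolated": bool(extrapolated),
        }
    return WeibullCurve(
        channel=channel,
        species=species,
        b=b,
        c=c,
        n_obs=len(tension),
        px_table=px_table,
        n_boot=n_boot,
        seed=seed,
        tension_max=t_max,
        extrapolation_warning=warn_flag,
    )


def per_tree_threshold_anova(
    per_tree_curves: dict[str, tuple[str, WeibullCurve]],
    x: float = 50.0,
) -> dict:
    """One-way ANOVA plus Tukey HSD of per-tree X% thresholds across
    species.

    ``per_tree_curves`` maps tree_id -> (species, fitted curve).  Species
    with fewer than two converged trees are excluded with a warning.
    """
    rows = [
        (tid, sp, curve.px(x)) for tid, (sp, curve) in per_tree_curves.items()
    ]
    df = pd.DataFrame(rows, columns=["tree_id", "species", "px"])
    counts = df["species"].value_counts()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(f"species excluded with < 2 converged trees: {thin}")
        df = df[~df["species"].isin(thin)]
    if df["species"].nunique() < 2:
        raise ValueError("need >= 2 species with >= 2 converged trees each")
    groups = [g["px"].to_numpy() for _, g in df.groupby("species")]
    species_names = sorted(df["species"].unique())
    if np.ptp(np.concatenate(groups)) == 0:
        # degenerate: every threshold identical -> no evidence of any effect
        f_stat, p = 0.0, 1.0
        pairs = [
            (a, b2, 0.0, 1.0)
            for i, a in enumerate(species_names)
            for b2 in species_names[i + 1:]
        ]
        tukey_df = pd.DataFrame(pairs, columns=["group1", "group2", "meandiff", "p-adj"])
    else:
        f_stat, p = f_oneway(*groups)
        tukey = pairwise_tukeyhsd(df["px"], df["species"])
        tukey_df = pd.DataFrame(
            tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
        )
    return {
        "x": x,
        "anova_f": float(f_stat),
        "anova_p": float(p),
        "tukey": tukey_df,
        "per_tree": df,
    }
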