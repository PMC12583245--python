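"""Tree water deficit (TWD), elastic storage and daily swelling/shrinkage
cycles from stem radius series.

TWD at any instant is the shortfall of the stem radius below its preceding
absolute maximum; it proxies the depletion of elastic water stores in the
living bark.  Tree water storage (TWS) is its complement within the
maximum storage capacity, and PLW_E = 100 * TWD / TWD_max rescales the
deficit to a 0-100% loss axis comparable with stomatal and hydraulic loss
curves.  TWD_max defaults to the global series maximum, appropriate when
stems were dried to complete elastic dehydration; an external override is
accepted for observational series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RadiusSeries",
    "TWDSeries",
    "DailyCycle",
    "compute_twd",
    "compute_plwe_at",
    "daily_extremes",
    "drought_cycles",
]


@dataclass
class RadiusSeries:
    """Regular-interval stem radius series for one tree (micrometres)."""

    tree_id: str
    species: str
    t: pd.DatetimeIndex
    r: np.ndarray

    def __post_init__(self) -> None:
        self.t = pd.DatetimeIndex(self.t)
        self.r = np.asarray(self.r, dtype=float)
        if len(self.t) != len(self.r):
            raise ValueError("t and r must have equal length")
        if len(self.t) >= 2:
            deltas = np.diff(self.t.asi8)
            if (deltas <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
            if not (deltas == deltas[0]).all():
                raise ValueError("timestamps must be equally spaced")

    @property
    def interval(self) -> pd.Timedelta:
        return pd.Timedelta(self.t.asi8[1] - self.t.asi8[0], unit="ns")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tree_id: str | None = None) -> "RadiusSeries":
        """Build from a long table with columns timestamp, tree_id,
        species, radius_um."""
        if tree_id is not None:
            df = df[df["tree_id"] == tree_id]
        if df.empty:
            raise ValueError(f"no rows for tree_id={tree_id!r}")
        df = df.sort_values("timestamp")
        return cls(
            tree_id=str(df["tree_id"].iloc[0]),
            species=str(df["species"].iloc[0]),
            t=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
            r=df["radius_um"].to_numpy(float),
        )


@dataclass
class TWDSeries:
    """Tree water deficit and derived storage series (micrometres, %)."""

    tree_id: str
    species: str
    t: pd.DatetimeIndex
    twd: np.ndarray
    tws: np.ndarray
    twd_max: float
    plwe: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.t,
                "tree_id": self.tree_id,
                "twd_um": self.twd,
                "tws_um": self.tws,
                "plwe_pct": self.plwe,
            }
        )


@dataclass
class DailyCycle:
    """Per-day TWD extremes and the derived swelling/shrinkage amounts."""

    date: pd.Timestamp
    twd_pd: float
    twd_md: float
    swelling: float = np.nan  # twd_md(d) - twd_pd(d+1), overnight recovery
    shrinkage: float = np.nan  # twd_md(d) - twd_pd(d), diurnal depletion
    swelling_norm: float = np.nan
    shrinkage_norm: float = np.nan
    degenerate: bool = field(default=False)


def compute_twd(
    series: RadiusSeries,
    twd_max: float | None = None,
    max_gap: pd.Timedelta | str = "60min",
) -> TWDSeries:
    """TWD(t) = max_{s<=t} r(s) - r(t), in one forward pass.

    NaN runs up to ``max_gap`` are linearly interpolated; longer runs are
    an error listing the gap.  The running maximum persists across
    interpolated gaps.  ``twd_max`` defaults to the series global maximum
    deficit (complete elastic dehydration); pass an external value for
    series that never fully dehydrated.
    """
    if len(series.r) < 2:
        raise ValueError("radius series needs at least 2 points")
    r = series.r.copy()
    if np.isnan(r).any():
        r = _fill_gaps(series.t, r, pd.Timedelta(max_gap))
    if not np.isfinite(r).all():
        raise ValueError("radius values must be finite")
    run_max = np.maximum.accumulate(r)
    twd = run_max - r
    observed_max = float(twd.max())
    if twd_max is None:
        twd_max = observed_max
    elif observed_max > twd_max:
        warnings.warn(
            f"observed TWD {observed_max:.2f} um exceeds supplied twd_max {twd_max:.2f} um; "
            "PLW_E will exceed 100%"
        )
    if twd_max <= 0:
        # flat or monotone-increasing series: no deficit ever develops
        plwe = np.zeros_like(twd)
        twd_max = 0.0
    else:
        plwe = 100.0 * twd / twd_max
    return TWDSeries(
        tree_id=series.tree_id,
        species=series.species,
        t=series.t,
        twd=twd,
        tws=twd_max - twd,
        twd_max=twd_max,
        plwe=plwe,
    )


def _fill_gaps(t: pd.DatetimeIndex, r: np.ndarray, max_gap: pd.Timedelta) -> np.ndarray:
    isnan = np.isnan(r)
    step = pd.Timedelta(t.asi8[1] - t.asi8[0], unit="ns")
    # locate contiguous NaN runs
    idx = np.flatnonzero(isnan)
    runs: list[tuple[int, int]] = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        runs = [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]
    too_long = [(a, b) for a, b in runs if (b - a + 1) * step > max_gap]
    if too_long:
        gaps = ", ".join(f"{t[a]}..{t[b]}" for a, b in too_long)
        raise ValueError(f"NaN gaps longer than {max_gap}: {gaps}")
    if runs:
        s = pd.Series(r, index=t).interpolate(method="time", limit_direction="both")
        return s.to_numpy()
    return r


def compute_plwe_at(twd_value: float, twd_max: float) -> float:
    """Percent loss of elastic water: 100 * twd / twd_max."""
    if twd_max <= 0:
        raise ValueError("twd_max must be > 0")
    if twd_value < 0:
        raise ValueError("twd_value must be >= 0")
    plwe = 100.0 * twd_value / twd_max
    if plwe > 100.0:
        warnings.warn("PLW_E exceeds 100%: twd_max is not the global maximum")
    return plwe


def _window_mask(t: pd.DatetimeIndex, window: tuple[int, int]) -> np.ndarray:
    hours = t.hour + t.minute / 60.0
    lo, hi = window
    return (hours >= lo) & (hours < hi)


def daily_extremes(
    twd_series: TWDSeries,
    predawn_window: tuple[int, int] = (3, 7),
    midday_window: tuple[int, int] = (12, 18),
    clip_negative_swelling: bool = False,
) -> list[DailyCycle]:
    """Predawn minimum and midday maximum TWD per day, with nocturnal
    swelling (recovery into the next predawn) and diurnal shrinkage.

    Days whose predawn or midday window holds no samples are dropped.
    Negative swelling (net overnight shrinkage under severe drought) is
    retained unless ``clip_negative_swelling``.
    """
    if predawn_window[0] < predawn_window[1] <= midday_window[0] < midday_window[1]:
        pass
    else:
        raise ValueError("windows must be ordered and non-overlapping within a day")
    t, twd = twd_series.t, twd_series.twd
    if (t[-1].normalize() - t[0].normalize()) < pd.Timedelta(days=1):
        raise ValueError("series must span at least 2 days")
    df = pd.DataFrame({"date": t.normalize(), "twd": twd})
    pd_mask = _window_mask(t, predawn_window)
    md_mask = _window_mask(t, midday_window)
    if not pd_mask.any() or not md_mask.any():
        raise ValueError("predawn/midday windows cover no samples")
    pred = df[pd_mask].groupby("date")["twd"].min()
    midd = df[md_mask].groupby("date")["twd"].max()
    both = pd.concat({"twd_pd": pred, "twd_md": midd}, axis=1).dropna()
    dropped = len(set(df["date"].unique()) - set(both.index))
    if dropped:
        warnings.warn(f"{dropped} day(s) dropped for missing window data")
    cycles: list[DailyCycle] = []
    dates = both.index
    for i, d in enumerate(dates):
        twd_pd_, twd_md_ = both.loc[d, "twd_pd"], both.loc[d, "twd_md"]
        shrink = twd_md_ - twd_pd_
        swell = np.nan
        nxt = d + pd.Timedelta(days=1)
        if nxt in both.index:
            swell = twd_md_ - both.loc[nxt, "twd_pd"]
            if clip_negative_swelling:
                swell = max(swell, 0.0)
        cycles.append(DailyCycle(date=d, twd_pd=float(twd_pd_), twd_md=float(twd_md_),
                                 swelling=float(swell), shrinkage=float(shrink)))
    return cycles


def drought_cycles(
    cycles: list[DailyCycle],
    radius: RadiusSeries,
) -> list[DailyCycle]:
    """Restrict daily cycles to the drought-induced shrinkage period after
    the tree's global radius maximum, then normalize swelling/shrinkage by
    tree-specific maxima over the retained period."""
    if not cycles or len(radius.r) == 0:
        raise ValueError("cycles and radius must be non-empty")
    peak_date = radius.t[int(np.argmax(radius.r))].normalize()
    kept = [c for c in cycles if c.date > peak_date]
    if not kept:
        warnings.warn("radius maximum on the final day: no drought period")
        return []
    sw = np.array([c.swelling for c in kept])
    sh = np.array([c.shrinkage for c in kept])
    sw_max = np.nanmax(sw) if not np.all(np.isnan(sw)) else np.nan
    sh_max = np.nanmax(sh) if not np.all(np.isnan(sh)) else np.nan
    degenerate_sw = not np.isfinite(sw_max) or sw_max <= 0
    degenerate_sh = not np.isfinite(sh_max) or sh_max <= 0
    if degenerate_sw or degenerate_sh:
        warnings.warn("degenerate normalization: non-positive maximum after filtering")
    out = []
    for c in kept:
        out.append(
            DailyCycle(
                date=c.date,
                twd_pd=c.twd_pd,
                twd_md=c.twd_md,
                swelling=c.swelling,
                shrinkage=c.shrinkage,
                swelling_norm=np.nan if degenerate_sw else c.swelling / sw_max,
                shrinkage_norm=np.nan if degenerate_sh else c.shrinkage / sh_max,
                degenerate=degenerate_sw or degenerate_sh,
            )
        )
    return out


def cycles_to_frame(cycles: list[DailyCycle], tree_id: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "date": [c.date for c in cycles],
            "twd_pd": [c.twd_pd for c in cycles],
            "twd_md": [c.twd_md for c in cycles],
            "swelling": [c.swelling for c in cycles],
            "shrinkage": [c.shrinkage for c in cycles],
            "swelling_norm": [c.swelling_norm for c in cycles],
            "shrinkage_norm": [c.shrinkage_norm for c in cycles],
        }
    )
    if tree_id:
        df.insert(0, "tree_id", tree_id)
    return df
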