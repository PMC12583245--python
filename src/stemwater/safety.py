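"""Dehydration and embolism safety areas (DSA, ESA) and the
drought-response sequence.

DSA integrates the gap between the stomatal-closure curve (PLG) and the
elastic-dehydration curve (PLW_E) over stem water potential from the
integration bound up to zero; ESA does the same against the embolism
curve (PLC).  The bound is the water potential at the first 88% threshold
reached while drying — the *less negative* of the PLW_E and PLC 88%
points — imposed to keep the ratio away from non-functional tension
ranges.  DSA/ESA > 1 means embolism precedes elastic dehydration
(hydration of living tissues is prioritized); < 1 the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from stemwater.plcurves import WeibullCurve

__all__ = [
    "SafetyAreas",
    "area_between",
    "dsa_esa",
    "stomatal_safety_margin",
    "classify_sequence",
]

DEFAULT_GRID_N = 2001


@dataclass
class SafetyAreas:
    species: str
    dsa: float  # %·MPa
    esa: float  # %·MPa
    ratio: float  # dsa / esa, nan when esa == 0
    psi_stop: float  # MPa, integration bound (<= 0)
    grid_n: int
    esa_zero: bool = False


def area_between(
    curve_a: WeibullCurve,
    curve_b: WeibullCurve,
    psi_stop: float,
    grid_n: int = DEFAULT_GRID_N,
) -> float:
    """Trapezoidal integral of PL_a(psi) - PL_b(psi) over [psi_stop, 0].

    Positive when ``curve_a`` loses earlier (at less negative psi) than
    ``curve_b``.  Uniform deterministic grid; the curves are smooth.
    """
    if psi_stop > 0:
        raise ValueError("psi_stop must be <= 0 MPa")
    if grid_n < 11:
        raise ValueError("grid_n must be >= 11")
    psi = np.linspace(psi_stop, 0.0, grid_n)
    diff = curve_a.pl(psi) - curve_b.pl(psi)
    return float(np.trapezoid(diff, psi))


def dsa_esa(
    plg: WeibullCurve,
    plwe: WeibullCurve,
    plc: WeibullCurve,
    grid_n: int = DEFAULT_GRID_N,
    threshold: float = 88.0,
) -> SafetyAreas:
    """DSA, ESA and their ratio down to the first 88% threshold.

    The integration bound is the less negative of the PLW_E and PLC
    88%-loss water potentials (the one reached first while drying).
    """
    t_stop = min(plwe.px(threshold), plc.px(threshold))
    psi_stop = -t_stop
    dsa = area_between(plg, plwe, psi_stop, grid_n)
    esa = area_between(plg, plc, psi_stop, grid_n)
    esa_zero = esa == 0.0
    if esa_zero:
        warnings.warn("ESA is zero: DSA/ESA ratio undefined")
    return SafetyAreas(
        species=plg.species or plwe.species or plc.species,
        dsa=dsa,
        esa=esa,
        ratio=np.nan if esa_zero else dsa / esa,
        psi_stop=psi_stop,
        grid_n=grid_n,
        esa_zero=esa_zero,
    )


def stomatal_safety_margin(
    plg: WeibullCurve,
    plc: WeibullCurve,
) -> tuple[float, bool]:
    """Signed-psi margin between complete stomatal closure and 50%
    conductivity loss: psi(PLG=95) - psi(PLC=50).

    Positive when stomata close before half the conductivity is lost.
    Returns (margin MPa, extrapolated flag); the flag is raised when
    either threshold lies beyond its curve's sampled tension range.
    """
    t95 = plg.px(95.0)
    t50 = plc.px(50.0)
    extrapolated = t95 > plg.tension_max or t50 > plc.tension_max
    return float(-t95 - (-t50)), bool(extrapolated)


def _interval(entry: dict) -> tuple[float, float]:
    est = entry["estimate"]
    lo = entry.get("ci_low")
    hi = entry.get("ci_high")
    if lo is None or hi is None:
        return (est, est)
    return (float(lo), float(hi))


def classify_sequence(thresholds: dict[str, dict]) -> str:
    """Order the three loss channels by their 50% tension.

    ``thresholds`` maps channel name (PLG, PLC, PLWE) to
    {estimate: tension -MPa, ci_low, ci_high}.  Adjacent channels whose
    95% CIs overlap are grouped as co-occurring, e.g.
    "PLG -> (PLC ~ PLWE)".
    """
    for ch in ("PLG", "PLC", "PLWE"):
        if ch not in thresholds:
            raise ValueError(f"missing channel {ch}")
    items = sorted(thresholds.items(), key=lambda kv: kv[1]["estimate"])
    groups: list[list[str]] = [[items[0][0]]]
    group_iv = [_interval(items[0][1])]
    for name, entry in items[1:]:
        lo, hi = _interval(entry)
        glo, ghi = group_iv[-1]
        if lo <= ghi and glo <= hi:  # CI overlap: co-occurring
            groups[-1].append(name)
            group_iv[-1] = (min(glo, lo), max(ghi, hi))
        else:
            groups.append([name])
            group_iv.append((lo, hi))
    parts = [
        g[0] if len(g) == 1 else "(" + " ~ ".join(g) + ")"
        for g in groups
    ]
    return " -> ".join(parts)
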