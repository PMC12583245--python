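"""Leaf pressure-volume (PV) curve analysis.

A bench-dried leaf is weighed and its water potential measured
repeatedly.  Plotting -1/|psi| against relative water deficit (1 - RWC)
makes the post-turgor-loss (purely osmotic) portion linear:
psi = pi100 / R implies -1/psi = R / |pi100|.  The osmotic potential at
full turgor, Pi_100, is -1/intercept of that line at 1 - RWC = 0; the
turgor loss point is the wettest point retained in the linear region,
evaluated on the osmotic line.  Saturated weight is estimated by
extrapolating fresh weight to psi = 0 over the wettest points
(oversaturation correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PVResult", "transform_pv_points", "fit_pv_curve"]


@dataclass
class PVResult:
    psi_tlp: float  # MPa < 0
    pi100: float  # MPa < 0
    sw: float  # saturated weight, g
    dw: float  # dry weight, g
    linear_region: np.ndarray  # indices into the transformed table
    r2_linear: float
    rwc_tlp: float
    n_linear: int


def transform_pv_points(
    points: pd.DataFrame,
    dw: float,
    n_saturation_points: int = 4,
    min_points: int = 6,
) -> tuple[pd.DataFrame, float]:
    """Transform bench-dry (fresh weight, psi) pairs to the PV plane.

    ``points`` needs columns fresh_weight_g and psi_mpa (< 0), wettest
    first.  Returns (table with columns x = 1 - RWC, y = -1/|psi|, rwc,
    psi_mpa, fresh_weight_g; estimated saturated weight).
    """
    fw = points["fresh_weight_g"].to_numpy(float)
    psi = points["psi_mpa"].to_numpy(float)
    if len(fw) < min_points:
        raise ValueError(f"need at least {min_points} PV points")
    if (psi >= 0).any():
        raise ValueError("psi must be < 0 MPa")
    if dw >= fw.min():
        raise ValueError("dry weight must be below every fresh weight")
    order = np.argsort(-psi)  # wettest (psi closest to 0) first
    fw, psi = fw[order], psi[order]
    if (np.diff(fw) > 1e-9 + 1e-6 * fw[0]).any():
        warnings.warn("fresh weight not monotonically decreasing while drying")

    k = min(n_saturation_points, len(fw))
    slope, icpt = np.polyfit(psi[:k], fw[:k], 1)
    sw = float(icpt) if slope > 0 else float(fw.max())
    if sw < fw.max():
        sw = float(fw.max())
    rwc = (fw - dw) / (sw - dw)
    out = pd.DataFrame(
        {
            "x": 1.0 - rwc,
            "y": -1.0 / psi,  # positive since psi < 0; inverse tension axis
            "rwc": rwc,
            "psi_mpa": psi,
            "fresh_weight_g": fw,
        }
    )
    return out, sw


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, icpt = np.polyfit(x, y, 1)
    yhat = icpt + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(icpt), float(slope), r2


def fit_pv_curve(
    transformed: pd.DataFrame,
    sw: float,
    dw: float,
    r2_min: float = 0.99,
    min_points: int = 4,
) -> PVResult:
    """Fit the osmotic line on the largest dry-end linear region.

    The region grows from the ``min_points`` driest points toward
    saturation; a wetter point joins only while the whole line keeps
    R^2 >= ``r2_min`` *and* the candidate's residual stays within three
    line-RMSEs (with a machine-precision floor), so the gently curved
    points just above turgor loss are excluded even on noiseless data.
    Pi_100 = -1/intercept; the turgor loss point is the osmotic-line
    value at the RWC of the wettest retained point.
    """
    df = transformed.sort_values("x").reset_index(drop=True)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    n = len(x)
    if n < min_points:
        raise ValueError(f"need at least {min_points} transformed points")
    start = n - min_points
    icpt, slope, r2 = _linfit(x[start:], y[start:])
    if r2 < r2_min:
        raise ValueError(
            f"no dry-end subset of >= {min_points} points reaches R^2 >= {r2_min}"
        )
    # noise scale from the driest points only (safely beyond turgor
    # loss), so the acceptance threshold is independent of how far the
    # region has grown
    k0 = min(min_points + 2, n)
    a0, b0, _ = _linfit(x[n - k0:], y[n - k0:])
    resid0 = y[n - k0:] - (a0 + b0 * x[n - k0:])
    sigma0 = float(np.sqrt(np.sum(resid0**2) / max(k0 - 2, 1)))
    # 4-sigma: false exclusion of a true line point is ~1e-4 per point,
    # while a pre-TLP point admitted this close to the line biases the
    # fit by at most ~threshold/k, vanishing with the noise
    threshold = max(4.0 * sigma0, 1e-8 * float(np.abs(y).mean()))
    while start > 0:
        cand = start - 1
        cand_resid = abs(y[cand] - (icpt + slope * x[cand]))
        icpt2, slope2, r22 = _linfit(x[cand:], y[cand:])
        if r22 >= r2_min and cand_resid <= threshold:
            start, icpt, slope, r2 = cand, icpt2, slope2, r22
        else:
            break
    if icpt <= 0:
        raise ValueError("osmotic line intercept must be positive (-1/psi axis)")
    pi100 = -1.0 / icpt
    # The turgor loss point lies between the wettest retained point and
    # its excluded (still-turgid) neighbour.  Pre-TLP points sit above
    # the osmotic line by a residual declining to zero at the TLP;
    # interpolating the two nearest excluded residuals to their zero
    # crossing gives a sub-grid estimate, clamped to the bracketing
    # interval so noise cannot push it past one sample spacing.
    x_tlp = float(x[start])
    if start >= 2:
        xb, xa = x[start - 1], x[start - 2]
        rb = y[start - 1] - (icpt + slope * xb)
        ra = y[start - 2] - (icpt + slope * xa)
        if ra > rb > 0:
            root = xb + rb * (xb - xa) / (ra - rb)
            x_tlp = float(np.clip(root, xb, x[start]))
    rwc_tlp = 1.0 - x_tlp
    psi_tlp = -1.0 / (icpt + slope * x_tlp)
    return PVResult(
        psi_tlp=float(psi_tlp),
        pi100=float(pi100),
        sw=float(sw),
        dw=float(dw),
        linear_region=np.arange(start, n),
        r2_linear=float(r2),
        rwc_tlp=rwc_tlp,
        n_linear=n - start,
    )
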