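"""Two-segment (breakpoint) linear models for daily swelling/shrinkage
dynamics.

The response declines steeply with the predictor (e.g. normalized
nocturnal swelling against PLW_E) until a breakpoint, then flattens.  The
breakpoint is estimated per species by a deterministic profile search
over a grid of candidates; at each candidate the continuous two-segment
model

    y = a + slope1 * min(x, xi) + slope2 * max(x - xi, 0)

is fitted and the SSE-minimizing candidate wins.  Tree-level effects are
estimated by a joint linear mixed model (random intercept and slope per
tree) when it converges, falling back to a two-stage scheme (per-tree
least squares at the shared breakpoint, species-level comparison over
tree slopes) when it does not — mixed fits on these data are prone to
convergence failure, so the path actually used is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["SegmentedFit", "fit_segmented", "compare_initial_slopes"]


@dataclass
class SegmentedFit:
    """One species' segmented fit."""

    response: str
    predictor: str
    species: str
    breakpoint: float
    intercept: float
    slope1: float
    slope2: float
    se1: float
    se2: float
    sse: float
    n: int
    path: str  # "mixed" or "two_stage"
    degenerate: bool = False
    converged: bool = True
    tree_slopes: dict[str, float] = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope1 * np.minimum(x, self.breakpoint)
            + self.slope2 * np.maximum(x - self.breakpoint, 0.0)
        )


def _design(x: np.ndarray, xi: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), np.minimum(x, xi), np.maximum(x - xi, 0.0)]
    )


def _profile_breakpoint(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray
) -> tuple[float, np.ndarray, float]:
    best = None
    for xi in grid:
        X = _design(x, xi)
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if best is None or sse < best[2] - 1e-13:
            best = (float(xi), beta, sse)
    return best


def _default_grid(x: np.ndarray, n: int = 101) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    span = hi - lo
    return np.linspace(lo + 0.1 * span, hi - 0.1 * span, n)


def fit_segmented(
    data: pd.DataFrame,
    response: str = "y",
    predictor: str = "x",
    breakpoint_grid: np.ndarray | None = None,
    min_points: int = 10,
    try_mixed: bool = True,
) -> dict[str, SegmentedFit]:
    """Fit the segmented model per species.

    ``data`` needs columns ``predictor``, ``response``, species, tree_id.
    Returns a map species -> :class:`SegmentedFit`.  One shared breakpoint
    per species; the fitted function is continuous at the breakpoint by
    construction.
    """
    fits: dict[str, SegmentedFit] = {}
    for sp, g in data.groupby("species"):
        g = g.dropna(subset=[predictor, response])
        x = g[predictor].to_numpy(float)
        y = g[response].to_numpy(float)
        if len(x) < max(min_points, 4):
            raise ValueError(f"species {sp}: fewer points ({len(x)}) than required")
        if np.ptp(x) == 0:
            raise ValueError(f"species {sp}: predictor is constant")
        grid = breakpoint_grid if breakpoint_grid is not None else _default_grid(x)
        xi, beta, sse = _profile_breakpoint(x, y, np.asarray(grid, float))
        degenerate = np.isclose(xi, grid[0]) or np.isclose(xi, grid[-1])
        if degenerate:
            warnings.warn(f"species {sp}: breakpoint pinned to grid boundary")

        path = "two_stage"
        se1 = se2 = np.nan
        if try_mixed and g["tree_id"].nunique() >= 3:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    X = _design(x, xi)
                    md = sm.MixedLM(
                        y, X, groups=g["tree_id"].to_numpy(),
                        exog_re=X[:, :2],  # random intercept + pre-break slope
                    )
                    mf = md.fit(reml=True, maxiter=200, method="lbfgs")
                if mf.converged and np.isfinite(mf.bse[:3]).all():
                    beta = mf.params[:3]
                    se1, se2 = float(mf.bse[1]), float(mf.bse[2])
                    path = "mixed"
            except Exception:
                path = "two_stage"
        tree_slopes = _per_tree_slopes(g, predictor, response, xi)
        if path == "two_stage":
            vals = np.array([v for v in tree_slopes.values() if np.isfinite(v)])
            if len(vals) >= 2:
                se1 = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            X = _design(x, xi)
            resid = y - X @ beta
            dof = max(len(x) - 3, 1)
            cov = np.linalg.pinv(X.T @ X) * float(resid @ resid) / dof
            se2 = float(np.sqrt(cov[2, 2]))
            if not np.isfinite(se1):
                se1 = float(np.sqrt(cov[1, 1]))
        fits[sp] = SegmentedFit(
            response=response,
            predictor=predictor,
            species=str(sp),
            breakpoint=xi,
            intercept=float(beta[0]),
            slope1=float(beta[1]),
            slope2=float(beta[2]),
            se1=se1,
            se2=se2,
            sse=sse,
            n=len(x),
            path=path,
            degenerate=bool(degenerate),
            tree_slopes=tree_slopes,
        )
    return fits


def _per_tree_slopes(
    g: pd.DataFrame, predictor: str, response: str, xi: float
) -> dict[str, float]:
    """Pre-break slope per tree from per-tree least squares at the shared
    breakpoint (segments with < 3 points fall back to the pre-break-only
    line)."""
    slopes: dict[str, float] = {}
    for tid, gt in g.groupby("tree_id"):
        x = gt[predictor].to_numpy(float)
        y = gt[response].to_numpy(float)
        pre = x <= xi
        if pre.sum() >= 2 and np.ptp(x[pre]) > 0:
            slopes[str(tid)] = float(np.polyfit(x[pre], y[pre], 1)[0])
        elif len(x) >= 2 and np.ptp(x) > 0:
            slopes[str(tid)] = float(np.polyfit(x, y, 1)[0])
        else:
            slopes[str(tid)] = np.nan
    return slopes


def compare_initial_slopes(fits: dict[str, SegmentedFit]) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparison of pre-break slopes across
    species, over tree-level slope estimates."""
    if len(fits) < 2:
        raise ValueError("need >= 2 species")
    rows = []
    for sp, f in fits.items():
        for tid, s in f.tree_slopes.items():
            if np.isfinite(s):
                rows.append((sp, tid, s))
    df = pd.DataFrame(rows, columns=["species", "tree_id", "slope1"])
    if df["species"].nunique() < 2:
        raise ValueError("need tree-level slopes for >= 2 species")
    if np.ptp(df["slope1"].to_numpy()) == 0:
        species = sorted(df["species"].unique())
        pairs = [
            (a, b, 0.0, 1.0)
            for i, a in enumerate(species)
            for b in species[i + 1:]
        ]
        return pd.DataFrame(pairs, columns=["group1", "group2", "meandiff", "p-adj"])
    tukey = pairwise_tukeyhsd(df["slope1"], df["species"])
    return pd.DataFrame(tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]])
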