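"""Relative aquaporin gene expression by the ddCt method, primer
efficiencies, and the expression-vs-water-potential model.

Each sample's target Ct (mean of >= 3 technical replicates) is
normalized to the mean Ct of two housekeeping genes (dCt).  The ddCt of
a sample is its dCt minus a control-period reference chosen so that the
arithmetic mean fold change of the control samples is exactly one (the
reference is the log2 of the mean control expression ratio, not the mean
control dCt — the distinction only matters in the presence of noise).
Fold change = 2^(-ddCt).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["delta_delta_ct", "primer_efficiency", "expression_psi_model"]


def delta_delta_ct(
    ct_table: pd.DataFrame,
    hk_genes: tuple[str, str] = ("RI18S", "ACT"),
    control_col: str = "is_control",
    spread_warn_ct: float = 0.5,
) -> pd.DataFrame:
    """Per-sample ddCt fold changes against two housekeeping genes.

    ``ct_table`` is long qPCR data with columns tree_id, species, date,
    gene, rep, ct, ``control_col`` and optionally psi_mpa.  Returns one
    record per sample x target gene with ct_mean, delta_ct,
    delta_delta_ct, fold_change and a replicate-spread warning flag.
    """
    if len(set(hk_genes)) < 2:
        raise ValueError("two distinct housekeeping genes are required")
    keys = ["tree_id", "date"]
    agg = (
        ct_table.groupby(keys + ["gene"])["ct"]
        .agg(ct_mean="mean", ct_spread=lambda s: s.max() - s.min(), n_reps="count")
        .reset_index()
    )
    meta_cols = [c for c in ("species", control_col, "psi_mpa") if c in ct_table.columns]
    meta = ct_table[keys + meta_cols].drop_duplicates(subset=keys)
    agg = agg.merge(meta, on=keys, how="left")

    hk = agg[agg["gene"].isin(hk_genes)]
    hk_wide = hk.pivot_table(index=keys, columns="gene", values="ct_mean")
    missing = [g for g in hk_genes if g not in hk_wide.columns]
    if missing or hk_wide[list(hk_genes)].isna().any().any():
        raise ValueError(f"housekeeping gene(s) missing for some samples: {missing or hk_genes}")
    hk_mean = hk_wide[list(hk_genes)].mean(axis=1).rename("hk_ct_mean")

    targets = agg[~agg["gene"].isin(hk_genes)].merge(hk_mean.reset_index(), on=keys)
    if targets.empty:
        raise ValueError("no target genes in ct_table")
    targets["delta_ct"] = targets["ct_mean"] - targets["hk_ct_mean"]
    targets["spread_flag"] = targets["ct_spread"] > spread_warn_ct
    if targets["spread_flag"].any():
        warnings.warn(
            f"{int(targets['spread_flag'].sum())} sample(s) with technical-replicate "
            f"spread > {spread_warn_ct} Ct"
        )
    group_cols = ["gene"] + (["species"] if "species" in targets.columns else [])
    out = []
    for _, g in targets.groupby(group_cols):
        ctrl = g[g[control_col].astype(bool)]
        if ctrl.empty:
            raise ValueError("no control samples for some species x gene group")
        # reference chosen so the arithmetic mean control fold change is 1
        ref = -np.log2(np.mean(2.0 ** (-ctrl["delta_ct"].to_numpy(float))))
        g = g.copy()
        g["delta_delta_ct"] = g["delta_ct"] - ref
        g["fold_change"] = 2.0 ** (-g["delta_delta_ct"])
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    res = res.rename(columns={control_col: "is_control"})
    drop = [c for c in ("ct_spread",) if c in res.columns]
    return res.drop(columns=drop)


def primer_efficiency(dilution_series: pd.DataFrame) -> float:
    """Amplification efficiency (%) from a cDNA dilution series.

    ``dilution_series`` has columns input_ng and ct.  The standard-curve
    slope of Ct on log10(input) gives efficiency
    (10^(-1/slope) - 1) * 100; a perfect template doubling per cycle
    yields slope -log2(10) ~ -3.32 and 100%.
    """
    ng = dilution_series["input_ng"].to_numpy(float)
    ct = dilution_series["ct"].to_numpy(float)
    if len(ng) < 3:
        raise ValueError("need >= 3 dilution points")
    if np.log2(ng.max() / ng.min()) < 2:
        raise ValueError("dilution series must span >= 2 two-fold steps")
    slope = np.polyfit(np.log10(ng), ct, 1)[0]
    if slope >= 0:
        raise ValueError("positive standard-curve slope: inverted dilution series")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


_TERMS = [
    "psi", "species", "gene",
    "psi:species", "psi:gene", "species:gene",
    "psi:species:gene",
]


def _contains(term_a: str, term_b: str) -> bool:
    """True when term_a's factors are a subset of term_b's."""
    a = set(term_a.split(":"))
    b = set(term_b.split(":"))
    return a < b


def _formula(terms: list[str], response: str) -> str:
    if not terms:
        return f"{response} ~ 1"
    parts = []
    for t in terms:
        parts.append(":".join(
            "C(species)" if f == "species" else "C(gene)" if f == "gene" else f
            for f in t.split(":")
        ))
    return f"{response} ~ " + " + ".join(parts)


def expression_psi_model(
    records: pd.DataFrame,
    response: str = "fold_change",
    log2_response: bool = False,
    alpha: float = 0.05,
    try_mixed: bool = True,
) -> dict:
    """Linear model of expression fold change against stem water
    potential with species and gene effects and backward selection.

    Starts from fold_change ~ psi * species * gene and iteratively
    removes the least significant removable term (p > alpha, marginality
    respected: a term is removable only when no retained interaction
    contains it).  A tree-level random-slope mixed model is attempted for
    the selected structure; on non-convergence the OLS fit stands
    (two-stage path) and per-tree slopes provide the species contrasts.
    """
    df = records.copy()
    need = {"psi_mpa", "species", "gene", "tree_id", response}
    if not need <= set(df.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    df = df.rename(columns={"psi_mpa": "psi"}).dropna(subset=["psi", response])
    if df["psi"].nunique() < 3:
        raise ValueError("need >= 3 distinct psi levels")
    if log2_response:
        df = df.assign(**{response: np.log2(df[response])})
    x = df[["psi"]].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < 2:
        raise ValueError("psi is collinear/constant")

    terms = list(_TERMS)
    if df["species"].nunique() < 2:
        terms = [t for t in terms if "species" not in t]
    if df["gene"].nunique() < 2:
        terms = [t for t in terms if "gene" not in t]
    dropped: list[str] = []
    while True:
        fit = smf.ols(_formula(terms, response), data=df).fit()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova = sm.stats.anova_lm(fit, typ=2)
        except Exception:
            break
        removable = [
            t for t in terms
            if not any(_contains(t, other) for other in terms if other != t)
        ]
        pvals = {}
        for t in removable:
            key = ":".join(
                "C(species)" if f == "species" else "C(gene)" if f == "gene" else f
                for f in t.split(":")
            )
            if key in anova.index:
                pvals[t] = float(anova.loc[key, "PR(>F)"])
        worst = max(pvals, key=pvals.get) if pvals else None
        if worst is None or pvals[worst] <= alpha:
            break
        terms.remove(worst)
        dropped.append(worst)

    final_ols = smf.ols(_formula(terms, response), data=df).fit()
    path = "ols"
    mixed_summary = None
    if try_mixed and df["tree_id"].nunique() >= 3:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    _formula(terms, response), data=df,
                    groups=df["tree_id"], re_formula="~psi",
                )
                mfit = md.fit(reml=True, maxiter=200, method="lbfgs")
            if mfit.converged:
                path = "mixed"
                mixed_summary = {
                    k: float(v) for k, v in mfit.params.items()
                }
        except Exception:
            path = "ols"

    # per-species slopes (pooling genes) and tree-level slopes for contrasts
    slopes: dict[str, float] = {}
    tree_rows = []
    for sp, g in df.groupby("species"):
        if g["psi"].nunique() >= 2:
            slopes[str(sp)] = float(np.polyfit(g["psi"], g[response], 1)[0])
        for tid, gt in g.groupby("tree_id"):
            if gt["psi"].nunique() >= 2:
                tree_rows.append((str(sp), str(tid),
                                  float(np.polyfit(gt["psi"], gt[response], 1)[0])))
    tree_slopes = pd.DataFrame(tree_rows, columns=["species", "tree_id", "slope"])
    contrasts = None
    if tree_slopes["species"].nunique() >= 2 and np.ptp(tree_slopes["slope"]) > 0:
        tk = pairwise_tukeyhsd(tree_slopes["slope"], tree_slopes["species"])
        contrasts = pd.DataFrame(tk.summary().data[1:],
                                 columns=[str(c) for c in tk.summary().data[0]])
    return {
        "terms": terms,
        "dropped": dropped,
        "psi_retained": any("psi" in t.split(":") for t in terms),
        "ols_params": {k: float(v) for k, v in final_ols.params.items()},
        "path": path,
        "mixed_params": mixed_summary,
        "species_slopes": slopes,
        "tree_slopes": tree_slopes,
        "slope_contrasts": contrasts,
        "n": len(df),
    }
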