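"""Distance-decay, temporal autocorrelation, and seasonal homogenization.

Community dissimilarity (Bray-Curtis) between pairs of samples from the same
forest is modelled as a linear function of the spatial distance between the
sampled trees (same-date pairs) or of the time between sampling dates.  A
declining mean within-date dissimilarity across the season is the
"homogenization" signature: communities converging as the growing season
progresses.

The OLS standard errors and ANOVA p-values treat pairs as independent
observations, as is conventional for these descriptive models even though
pairs sharing a sample are correlated; an optional Mantel-style permutation
p-value (permuting sample identities) is available as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["build_pairs", "autocorr_fit", "homogenization_trend", "AutocorrFit"]

_FORMULAS = {
    "BC~pDist*D": "BC ~ pDist * Date",
    "BC~pDist": "BC ~ pDist",
    "BC~pTime": "BC ~ pTime",
}


def build_pairs(d: pd.DataFrame, meta: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Enumerate eligible within-forest sample pairs with their BC values.

    ``mode="spatial"`` keeps same-forest, same-date pairs and computes the
    Euclidean distance (pDist, meters) between the two trees; ``mode=
    "temporal"`` keeps all same-forest pairs and computes the absolute date
    difference (pTime, days).
    """
    if mode not in {"spatial", "temporal"}:
        raise ValueError(f"mode must be 'spatial' or 'temporal', got {mode!r}")
    meta = meta.reindex(d.index)
    for col in ("x", "y") if mode == "spatial" else ():
        if col not in meta.columns or meta[col].isna().any():
            bad = list(meta.index[meta.get(col, pd.Series(index=meta.index)).isna()])
            raise ValueError(f"missing coordinate {col!r} for samples {bad}")
    ids = np.array(d.index)
    forest = meta["F"].to_numpy()
    date = meta["D"].to_numpy(dtype=float)
    dm = d.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(ids), k=1)
    same_forest = forest[iu] == forest[ju]
    rows: dict[str, np.ndarray]
    if mode == "spatial":
        x = meta["x"].to_numpy(dtype=float)
        y = meta["y"].to_numpy(dtype=float)
        keep = same_forest & (date[iu] == date[ju])
        i, j = iu[keep], ju[keep]
        rows = {
            "a": ids[i],
            "b": ids[j],
            "forest": forest[i],
            "Date": date[i],
            "pDist": np.hypot(x[i] - x[j], y[i] - y[j]),
            "BC": dm[i, j],
        }
    else:
        keep = same_forest
        i, j = iu[keep], ju[keep]
        rows = {
            "a": ids[i],
            "b": ids[j],
            "forest": forest[i],
            "pTime": np.abs(date[i] - date[j]),
            "BC": dm[i, j],
        }
    return pd.DataFrame(rows)


@dataclass
class AutocorrFit:
    """OLS fit of pairwise BC on distance and/or time predictors."""

    formula: str
    params: pd.Series
    bse: pd.Series
    anova_p: pd.Series
    n_pairs: int
    model: object

    @property
    def stars(self) -> pd.Series:
        return self.anova_p.map(
            lambda p: "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        )

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.params, "se": self.bse})
        out["anova_p"] = self.anova_p.reindex(out.index)
        return out


def autocorr_fit(pairs: pd.DataFrame, formula: str = "BC~pDist") -> AutocorrFit:
    """Fit one of the linear autocorrelation models to a pair table.

    Supported formulas: ``BC~pDist`` (spatial decay at one date),
    ``BC~pDist*D`` (spatial decay with date and interaction), ``BC~pTime``
    (temporal decay).  Estimates and standard errors come from OLS; per-term
    p-values from a sequential ANOVA F-test.
    """
    if formula not in _FORMULAS:
        raise ValueError(f"formula must be one of {sorted(_FORMULAS)}")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to fit")
    predictor = "pTime" if "pTime" in formula else "pDist"
    if np.isclose(pairs[predictor].var(), 0):
        raise ValueError(f"degenerate fit: predictor {predictor} has no variance")
    fit = smf.ols(_FORMULAS[formula], data=pairs).fit()
    av = anova_lm(fit, typ=1)
    anova_p = av["PR(>F)"].drop("Residual")
    return AutocorrFit(
        formula=formula,
        params=fit.params,
        bse=fit.bse,
        anova_p=anova_p,
        n_pairs=len(pairs),
        model=fit,
    )


def homogenization_trend(d: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-forest seasonal trend in mean within-date community dissimilarity.

    For each forest, within-date sample pairs are pooled and their BC values
    regressed on the day of year; the per-date mean BC values are reported
    alongside the fitted trend (slope, its standard error, and the OLS
    p-value computed at the pair level).  Dates with fewer than two samples
    contribute no pairs and are dropped.

    Returns a tidy frame with one row per (forest, date) plus the forest-level
    slope columns repeated on each row.
    """
    pairs = build_pairs(d, meta, mode="spatial")  # same-forest, same-date pairs
    rows = []
    for forest, sub in pairs.groupby("forest"):
        means = sub.groupby("Date")["BC"].mean()
        if sub["Date"].nunique() < 2:
            raise ValueError(f"forest {forest!r} has fewer than 2 dates with pairs")
        X = sm.add_constant(sub["Date"].to_numpy())
        fit = sm.OLS(sub["BC"].to_numpy(), X).fit()
        slope, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        for date, mean_bc in means.items():
            rows.append(
                {
                    "forest": forest,
                    "D": date,
                    "mean_BC": mean_bc,
                    "n_pairs": int((sub["Date"] == date).sum()),
                    "slope": slope,
                    "slope_se": se,
                    "slope_p": p,
                    "direction": "-" if slope < 0 else "+",
                }
            )
    return pd.DataFrame(rows)
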