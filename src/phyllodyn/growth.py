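"""Colony growth phenotyping from plate-photo time series.

Pipeline: quantify spot intensities (with per-image smooth-background
subtraction), correct for position-dependent competition between
neighbouring colonies, fit a logistic growth curve per spot, and partition
the variance of log yield and log growth rate across genetic and
environmental factors.

Yield Y is the logistic asymptote of spot intensity (arbitrary intensity
units).  The growth rate r is the inverse of the total time needed to reach
the yield: lag phase plus exponential phase, operationalized as
``t_Y = t_mid + ln(19)/k`` (the time to reach 95% of Y) and ``r = 1/t_Y``
(per day).  Both are replicate-averaged per isolate x treatment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar
from scipy.stats import f as f_dist

from ._design import build_sequential_design, term_dummies
from .synthetic_data import logistic_intensity

__all__ = [
    "quantify_spots",
    "competition_correct",
    "fit_growth",
    "growth_anova",
    "summarize_growth",
    "load_growth_table",
    "TABLE3_TERMS",
]

log = logging.getLogger(__name__)

#: factor order for the growth variance partition: forest, host, date,
#: preconditioning/monitoring/isolation temperatures, clade, then the listed
#: interactions; everything else is pooled as "other interactions".
TABLE3_TERMS = [
    "F", "H", "D", "T_P", "T_M", "T_I", "C",
    "F:D", "H:D", "H:C", "D:C", "F:C", "F:T_I", "H:T_I", "C:T_I",
    "F:H:D", "F:H:C", "F:D:C", "H:D:C", "H:D:T_I",
]


def _fit_background(img: np.ndarray, mask: np.ndarray, degree: int = 2) -> np.ndarray:
    """Least-squares 2-D polynomial surface fitted to unmasked pixels."""
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    cx = xx / img.shape[1] - 0.5
    cy = yy / img.shape[0] - 0.5
    terms = [np.ones_like(cx), cx, cy]
    if degree >= 2:
        terms += [cx * cy, cx**2, cy**2]
    A = np.stack([t[mask] for t in terms], axis=1)
    coef, *_ = np.linalg.lstsq(A, img[mask], rcond=None)
    full = np.stack([t.ravel() for t in terms], axis=1)
    return (full @ coef).reshape(img.shape)


def quantify_spots(
    images: dict,
    layout: pd.DataFrame,
    background: str = "poly2",
    mask_factor: float = 1.6,
) -> pd.DataFrame:
    """Per-spot intensity at each time point, background-corrected.

    ``images`` maps (plate, time) to a 2-D array registered to the layout's
    pixel frame.  Raw intensity is the pixel sum within the spot disc; the
    background is a low-order polynomial fitted per image to inter-spot
    pixels (discs dilated by ``mask_factor``) and subtracted pixel-wise
    before summing.  Returns a tidy frame: spot, plate, time, raw, intensity.
    """
    rows = []
    for (plate, t), img in sorted(images.items()):
        sub = layout[layout["plate"] == plate]
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        spot_mask = np.zeros(img.shape, dtype=bool)
        for _, spot in sub[sub["occupied"]].iterrows():
            if (
                spot["cx"] - spot["radius"] < 0
                or spot["cy"] - spot["radius"] < 0
                or spot["cx"] + spot["radius"] >= img.shape[1]
                or spot["cy"] + spot["radius"] >= img.shape[0]
            ):
                raise ValueError(f"spot {spot.name} disc extends outside the image")
            spot_mask |= (xx - spot["cx"]) ** 2 + (yy - spot["cy"]) ** 2 <= (
                mask_factor * spot["radius"]
            ) ** 2
        if background == "poly2":
            bg = _fit_background(img, ~spot_mask)
        elif background == "none":
            bg = np.zeros_like(img)
        else:
            raise ValueError(f"unknown background model {background!r}")
        corrected = img - bg
        for spot_id, spot in sub.iterrows():
            disc = (xx - spot["cx"]) ** 2 + (yy - spot["cy"]) ** 2 <= spot["radius"] ** 2
            raw = float(img[disc].sum())
            val = float(corrected[disc].sum())
            rows.append(
                {
                    "spot": spot_id,
                    "plate": plate,
                    "row": spot["row"],
                    "col": spot["col"],
                    "isolate": spot["isolate"],
                    "treatment": spot["treatment"],
                    "replicate": spot["replicate"],
                    "occupied": spot["occupied"],
                    "time": float(t),
                    "raw": raw,
                    "intensity": max(val, 0.0),
                }
            )
            if val < 0:
                log.debug("spot %s at t=%s clipped to 0 (was %.3g)", spot_id, t, val)
    return pd.DataFrame(rows)


def _neighbour_load(series: pd.DataFrame) -> pd.Series:
    """Neighbourhood load N_i = sum_j I_j / dist_ij over occupied co-plated spots."""
    out = pd.Series(0.0, index=series.index)
    for (_, _), sub in series.groupby(["plate", "time"]):
        occ = sub[sub["occupied"]]
        coords = occ[["row", "col"]].to_numpy(dtype=float)
        inten = occ["intensity"].to_numpy()
        if len(occ) < 2:
            continue
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        with np.errstate(divide="ignore"):
            w = 1.0 / dist
        np.fill_diagonal(w, 0.0)
        out.loc[occ.index] = w @ inten
    return out


def competition_correct(
    series: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    c: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Invert position-dependent competition between neighbouring colonies.

    The suppression model is ``I_obs = I_true / (1 + c * N)`` with
    neighbourhood load ``N_i = sum_j I_obs_j / dist(i, j)`` over occupied
    spots on the same plate (grid-cell distances).  Because the load is
    defined on observed intensities, the inversion is exact given ``c``:
    ``I_true = I_obs * (1 + c * N)``.

    When ``c`` is not supplied it is estimated by least squares on replicate
    consistency: replicates of the same isolate x treatment at different grid
    positions should recover identical true intensities, so ``c`` minimizes
    the summed within-replicate-group variance of corrected intensities.

    Returns the corrected series (column ``intensity`` replaced, raw kept in
    ``intensity_obs``) and the ``c`` used.
    """
    series = series.copy()
    load = _neighbour_load(series)
    occ = series["occupied"]

    if c is None:
        groups = series[occ].groupby(["isolate", "treatment", "time"])
        if (groups["spot"].count() if "spot" in series else groups.size()).max() < 2:
            log.warning("no replicated spots: competition coefficient unidentifiable, skipped")
            series["intensity_obs"] = series["intensity"]
            return series, 0.0
        i_obs = series.loc[occ, "intensity"].to_numpy()
        n_load = load[occ].to_numpy()
        key = series.loc[occ, ["isolate", "treatment", "time"]].astype(str).agg("|".join, axis=1)
        codes, _ = pd.factorize(key)
        counts = np.bincount(codes)

        def objective(cc):
            # absolute residuals: high-intensity groups carry the smallest
            # relative noise and should dominate the fit
            corr = i_obs * (1.0 + cc * n_load)
            mean = np.bincount(codes, weights=corr) / counts
            resid = corr - mean[codes]
            return float((resid**2).sum())

        res = minimize_scalar(objective, bounds=(0.0, 2.0), method="bounded",
                              options={"xatol": 1e-8})
        c = float(res.x)
        log.info("estimated competition coefficient c = %.5f", c)

    series["intensity_obs"] = series["intensity"]
    series.loc[occ, "intensity"] = series.loc[occ, "intensity"] * (1.0 + c * load[occ])
    return series, c


def fit_growth(
    series: pd.DataFrame,
    origin_anchor: bool = True,
    detection_threshold: float = 1e-6,
    yield_fraction: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit logistic growth curves per spot and average replicates.

    Each occupied spot's intensities I(t) are fitted with
    ``I(t) = Y / (1 + exp(-k (t - t_mid)))`` by least squares, anchored at
    I(0) = 0 when ``origin_anchor`` so three photo time points identify the
    three parameters.  Derived quantities: lag = t_mid - 2/k (tangent
    construction), t_Y = time to reach ``yield_fraction`` of Y, r = 1/t_Y.
    Spots whose maximum intensity is below ``detection_threshold`` times the
    plate-series maximum get Y = 0 and missing r.  Non-converging fits retry
    from a grid of initial values and are flagged missing if still failing.

    Returns ``(per_spot, per_isolate)`` with per-isolate x treatment means.
    """
    logit_q = np.log(yield_fraction / (1 - yield_fraction))
    floor = detection_threshold * max(series["intensity"].max(), 1.0)
    rows = []
    for spot_id, sub in series[series["occupied"]].groupby("spot", sort=False):
        sub = sub.sort_values("time")
        t = sub["time"].to_numpy(dtype=float)
        i = sub["intensity"].to_numpy(dtype=float)
        if len(t) < (3 if origin_anchor else 4):
            raise ValueError(f"spot {spot_id}: need at least 3 time points")
        if origin_anchor:
            t = np.concatenate([[0.0], t])
            i = np.concatenate([[0.0], i])
        base = {
            "spot": spot_id,
            "isolate": sub["isolate"].iloc[0],
            "treatment": sub["treatment"].iloc[0],
            "replicate": sub["replicate"].iloc[0],
        }
        if i.max() < floor:
            rows.append({**base, "Y": 0.0, "k": np.nan, "t_mid": np.nan,
                         "lag": np.nan, "t_Y": np.nan, "r": np.nan, "rss": 0.0})
            continue
        fit = None
        inits = [(i.max(), k0, tm) for k0 in (0.3, 0.6, 1.0, 0.15)
                 for tm in (0.5 * t.max(), 0.3 * t.max())]
        for p0 in inits:
            try:
                popt, _ = curve_fit(
                    logistic_intensity, t, i, p0=p0,
                    bounds=([0, 1e-3, 0], [np.inf, 10.0, 10 * t.max()]),
                    maxfev=5000,
                )
                rss = float(((logistic_intensity(t, *popt) - i) ** 2).sum())
                if fit is None or rss < fit[1]:
                    fit = (popt, rss)
            except RuntimeError:
                continue
        if fit is None:
            log.warning("spot %s: logistic fit failed", spot_id)
            rows.append({**base, "Y": np.nan, "k": np.nan, "t_mid": np.nan,
                         "lag": np.nan, "t_Y": np.nan, "r": np.nan, "rss": np.nan})
            continue
        (Y, k, t_mid), rss = fit
        t_y = t_mid + logit_q / k
        rows.append(
            {
                **base,
                "Y": Y,
                "k": k,
                "t_mid": t_mid,
                "lag": t_mid - 2.0 / k,
                "t_Y": t_y,
                "r": 1.0 / t_y if t_y > 0 else np.nan,
                "rss": rss,
            }
        )
    per_spot = pd.DataFrame(rows)
    per_isolate = (
        per_spot.groupby(["isolate", "treatment"], sort=True)[["Y", "k", "t_mid", "r"]]
        .mean()
        .reset_index()
    )
    return per_spot, per_isolate


def _sequential_anova(y: np.ndarray, meta: pd.DataFrame, terms: list[str],
                      pool_other: bool = True) -> pd.DataFrame:
    """Univariate sequential (Type-I) ANOVA with SS fractions.

    After the listed terms, the remaining between-cell variation (cells =
    full crossing of all factors appearing in any term) is pooled as "other
    interactions"; the residual is the within-cell variation.
    """
    n = len(y)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    design = build_sequential_design(meta.reset_index(drop=True), terms)
    proj = design.basis.T @ yc
    ss_terms = np.array([float((proj[sl] ** 2).sum()) for sl in design.slices])
    df_terms = np.array(design.df, dtype=float)
    rank_listed = design.rank

    rows = []
    if pool_other:
        factors = sorted({c for t in terms for c in t.split(":")})
        cells = term_dummies(meta.reset_index(drop=True), ":".join(factors))
        # SS of the full cell-mean model
        counts = cells.sum(axis=0)
        means = (cells.T @ yc) / counts
        ss_cells = float((counts * means**2).sum())
        df_cells = int((counts > 0).sum()) - 1
        ss_other = max(ss_cells - ss_terms.sum(), 0.0)
        df_other = max(df_cells - rank_listed, 0)
        ss_resid = ss_total - ss_cells
        df_resid = n - 1 - df_cells
    else:
        ss_other, df_other = 0.0, 0
        ss_resid = ss_total - ss_terms.sum()
        df_resid = n - 1 - rank_listed

    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    for term, ss, df in zip(terms, ss_terms, df_terms):
        if df == 0:
            log.warning("term %s aliased; pooled into other interactions", term)
            rows.append({"term": term, "df": 0, "SS": 0.0, "fraction": 0.0,
                         "F": np.nan, "p": np.nan})
            continue
        F = (ss / df) / ms_resid if ms_resid and ms_resid > 0 else 0.0
        p = float(f_dist.sf(F, df, df_resid)) if df_resid > 0 else np.nan
        rows.append({"term": term, "df": int(df), "SS": ss,
                     "fraction": ss / ss_total if ss_total > 0 else 0.0, "F": F, "p": p})
    if pool_other:
        rows.append({"term": "other interactions", "df": df_other, "SS": ss_other,
                     "fraction": ss_other / ss_total if ss_total > 0 else 0.0,
                     "F": np.nan, "p": np.nan})
    rows.append({"term": "Residual", "df": int(df_resid), "SS": ss_resid,
                 "fraction": ss_resid / ss_total if ss_total > 0 else 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def growth_anova(
    fits: pd.DataFrame,
    iso: pd.DataFrame,
    terms: list[str] | None = None,
    pool_other: bool = True,
) -> dict[str, pd.DataFrame]:
    """Partition variance in log Y and log r across genetic/environmental factors.

    ``fits`` is the per-isolate x treatment table from :func:`fit_growth`;
    ``iso`` the isolate metadata (clade C, forest F, host H, date D,
    isolation temperature T_I).  Treatment codes like ``P20M30`` provide the
    preconditioning (T_P) and monitoring (T_M) temperatures.  Y and r are
    log-transformed; rows with nonpositive or missing values are dropped.
    Sequential sums of squares follow the given term order (default
    :data:`TABLE3_TERMS`); unlisted interactions are pooled.

    Returns ``{"Y": table, "r": table}`` of SS fractions, F and p per term.
    """
    terms = list(terms) if terms is not None else list(TABLE3_TERMS)
    data = fits.merge(iso, on="isolate", how="left", suffixes=("", "_iso"))
    data["T_P"] = data["treatment"].str.slice(1, 3)
    data["T_M"] = data["treatment"].str.slice(4, 6)
    needed = sorted({c for t in terms for c in t.split(":")})
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"metadata columns missing for terms: {missing}")
    terms = [t for t in terms
             if all(data[c].nunique() > 1 for c in t.split(":"))]
    out = {}
    for response in ("Y", "r"):
        sub = data[np.isfinite(data[response]) & (data[response] > 0)].copy()
        y = np.log(sub[response].to_numpy(dtype=float))
        out[response] = _sequential_anova(y, sub[needed], terms, pool_other=pool_other)
    return out


def summarize_growth(
    fits: pd.DataFrame,
    iso: pd.DataFrame | None = None,
    grouping: str | list[str] = "C",
) -> pd.DataFrame:
    """Group means and SDs of yield and rate on the natural scale.

    ``grouping`` names metadata/fit columns (e.g. ``"C"`` for clade,
    ``"treatment"``, or ``["F", "D"]``).  Empty groups are simply absent.
    """
    data = fits if iso is None else fits.merge(iso, on="isolate", how="left")
    if isinstance(grouping, str):
        grouping = [grouping]
    if "T_M" in grouping and "T_M" not in data.columns:
        data = data.copy()
        data["T_M"] = data["treatment"].str.slice(4, 6)
    agg = data.groupby(grouping)[["Y", "r"]].agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg


def load_growth_table(path) -> pd.DataFrame:
    """Read a replicate-averaged growth table (TSV).

    Expected columns: isolate, treatment (or T_P/T_M), Y, r, plus any
    metadata columns (C, F, H, D, T_I).  This is the layout of a
    per-isolate-by-treatment summary such as a published supplementary
    growth table exported to TSV.
    """
    df = pd.read_csv(path, sep="\t")
    if "treatment" not in df.columns and {"T_P", "T_M"}.issubset(df.columns):
        df["treatment"] = "P" + df["T_P"].astype(str) + "M" + df["T_M"].astype(str)
    required = {"isolate", "Y", "r"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    return df
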