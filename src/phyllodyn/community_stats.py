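"""Community dissimilarity statistics: PERMANOVA, depth scan, PCA, taxon tests.

The central tool is a sequential-partition PERMANOVA on a distance matrix
(Gower-centered inner products, Type-I sums of squares by projection, free
row permutation), applied either directly to a sample-by-taxon table or along
a grid of phylogenetic similarity thresholds (the "depth scan"), where the
community is re-tabulated at every taxon granularity the tree allows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from ._design import build_sequential_design
from .phylo_structure import slice_taxa

__all__ = [
    "hellinger",
    "bray_curtis",
    "permanova",
    "depth_scan",
    "pca",
    "asv_factor_tests",
    "PermanovaResult",
]

log = logging.getLogger(__name__)


def hellinger(m: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of per-sample relative abundance.

    Each output row has unit Euclidean norm.
    """
    values = m.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table has negative entries")
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = list(m.index[zero])
        raise ValueError(f"all-zero rows cannot be Hellinger-transformed: {bad}")
    return pd.DataFrame(np.sqrt(values / sums[:, None]), index=m.index, columns=m.columns)


def bray_curtis(m: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity BC(a,b) = sum|a-b| / sum(a+b) between rows."""
    values = m.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table has negative entries")
    row_zero = values.sum(axis=1) == 0
    if row_zero.sum() >= 2:
        bad = list(m.index[row_zero])
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus the inputs needed to reproduce it."""

    table: pd.DataFrame
    n_perm: int
    terms: list[str]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_perm={self.n_perm})\n{self.table}"


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    return h @ a @ h


def permanova(
    d: pd.DataFrame,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    permutations: str = "free",
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential variance partitioning.

    The squared distance matrix is Gower-centered into an inner-product
    matrix G; each term's sum of squares is the trace of G projected onto the
    design directions that term adds beyond everything before it (Type-I, so
    the term order matters and is part of the analysis).  Pseudo-F compares
    each term's mean square to the residual mean square; p-values come from
    free permutation of rows, with the +1 correction.

    Parameters
    ----------
    d : square distance matrix (samples x samples).
    meta : per-sample metadata aligned to ``d`` (reindexed by d's index).
    terms : ordered model terms; ``"F:H"`` denotes an interaction.
    permutations : ``"free"`` (Monte Carlo, needs ``seed``) or ``"exhaustive"``
        (all n! row orders; only sensible for n <= 8).

    Aliased terms (no new degrees of freedom) get NaN statistics and a warning.
    """
    meta = meta.reindex(d.index)
    if meta.isna().any().any():
        raise ValueError("metadata missing for some samples in the distance matrix")
    n = len(d)
    G = _gower_center(d.to_numpy(dtype=float))
    ss_total = float(np.trace(G))
    design = build_sequential_design(meta.reset_index(drop=True), terms)
    if n < design.rank + 2:
        raise ValueError(f"n={n} too small for a model with {design.rank} df")
    U = design.basis

    def term_ss(Uperm: np.ndarray) -> np.ndarray:
        contrib = np.einsum("ij,ij->j", Uperm, G @ Uperm)
        return np.array([contrib[sl].sum() for sl in design.slices])

    ss = term_ss(U)
    df = np.array(design.df, dtype=float)
    df_res = n - 1 - design.rank
    ss_res = ss_total - ss.sum()
    aliased = df == 0
    if aliased.any():
        log.warning("aliased terms (0 df): %s", [t for t, a in zip(terms, aliased) if a])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss / df) / (ss_res / df_res)

    if permutations == "exhaustive":
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        count = np.zeros(len(terms))
        for p in perms:
            ssp = term_ss(U[p])
            ss_res_p = ss_total - ssp.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                fp = (ssp / df) / (ss_res_p / df_res)
            count += fp >= f_obs - 1e-9 * (1 + np.abs(f_obs))
        pvals = count / len(perms)
        n_perm_used = len(perms)
    else:
        if seed is None:
            raise ValueError("seed is required for Monte Carlo permutations")
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            ssp = term_ss(U[p])
            ss_res_p = ss_total - ssp.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                fp = (ssp / df) / (ss_res_p / df_res)
            count += fp >= f_obs - 1e-9 * (1 + np.abs(f_obs))
        pvals = (1 + count) / (n_perm + 1)
        n_perm_used = n_perm

    r2 = ss / ss_total
    r2[aliased] = np.nan
    f_obs = np.where(aliased, np.nan, f_obs)
    pvals = np.where(aliased, np.nan, pvals)
    rows = list(zip(terms, df, ss, r2, f_obs, pvals))
    rows.append(("Residual", float(df_res), ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", float(n - 1), ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "pseudo_F", "p"]).set_index(
        "term"
    )
    return PermanovaResult(table=table, n_perm=n_perm_used, terms=list(terms))


def aggregate_isolates(
    isolates: pd.DataFrame,
    partition,
    group_cols: tuple[str, ...] = ("tree", "D", "T_I"),
    factor_cols: tuple[str, ...] = ("F", "T_I", "D", "H"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate isolate taxa into per-group absolute abundance.

    Isolates are grouped by ``group_cols`` (default: host tree x sampling
    date x isolation temperature, the finest observational unit the isolate
    table supports); each group becomes one community whose factor levels are
    taken from its isolates.
    """
    iso = isolates.copy()
    if "isolate" in iso.columns:
        iso = iso.set_index("isolate")
    iso["_taxon"] = [partition.assignments[i] for i in iso.index]
    iso["_group"] = iso[list(group_cols)].astype(str).agg("|".join, axis=1)
    counts = pd.crosstab(iso["_group"], iso["_taxon"])
    gmeta = iso.groupby("_group")[list(dict.fromkeys(factor_cols))].first()
    return counts, gmeta.reindex(counts.index)


def depth_scan(
    utree,
    isolates: pd.DataFrame,
    terms: list[str] = ("F", "T_I", "D", "H"),
    ps_grid: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
    group_cols: tuple[str, ...] = ("tree", "D", "T_I"),
) -> pd.DataFrame:
    """PERMANOVA along a grid of phylogenetic similarity thresholds.

    For each grid value the tree is sliced into taxa, isolates are tabulated
    into per-group abundance, Hellinger-transformed, converted to Bray-Curtis
    distances, and partitioned by a sequential PERMANOVA.  The default grid
    spans 0.926 to 1.000 in steps of 0.001 (clipped to the root height).

    Returns a long table with one row per (PS value, term).
    """
    root_h = utree.seed_node.ps_height
    if ps_grid is None:
        ps_grid = np.round(np.arange(0.926, 1.0 + 1e-9, 0.001), 6)
        ps_grid = ps_grid[ps_grid >= root_h - 1e-12]
    else:
        ps_grid = np.asarray(ps_grid, dtype=float)
        if (ps_grid < root_h - 1e-12).any():
            raise ValueError("grid values below the root height are undefined")
    terms = list(terms)
    rows = []
    rng = np.random.default_rng(seed)
    for ps in ps_grid:
        partition = slice_taxa(utree, float(ps))
        counts, gmeta = aggregate_isolates(isolates, partition, group_cols=group_cols)
        if counts.shape[1] < 2 or len(counts) < 4:
            continue
        usable = [
            t for t in terms if all(gmeta[c].nunique() > 1 for c in t.split(":"))
        ]
        if not usable:
            continue
        d = bray_curtis(hellinger(counts))
        res = permanova(d, gmeta, usable, n_perm=n_perm, seed=int(rng.integers(2**31)))
        for term in usable:
            rows.append(
                {
                    "ps": float(ps),
                    "term": term,
                    "R2": res.table.loc[term, "R2"],
                    "p": res.table.loc[term, "p"],
                    "n_taxa": partition.n_taxa,
                }
            )
    return pd.DataFrame(rows)


def pca(m: pd.DataFrame):
    """PCA of relative abundances via column-centered SVD.

    Returns an object with ``scores`` (samples x components), ``loadings``
    (taxa x components) and ``explained`` (variance fractions, summing to 1).
    """
    if len(m) < 2:
        raise ValueError("PCA needs at least two samples")
    values = m.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    rel = np.divide(values, sums, out=np.zeros_like(values), where=sums > 0)
    centered = rel - rel.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    from types import SimpleNamespace

    k = len(s)
    comp = [f"PC{i + 1}" for i in range(k)]
    return SimpleNamespace(
        scores=pd.DataFrame(u * s, index=m.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=m.columns, columns=comp),
        explained=pd.Series(explained, index=comp),
    )


def asv_factor_tests(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-taxon tests of relative abundance against forest and season.

    For each taxon: a one-way ANOVA of relative abundance on forest F
    (direction = level with the higher mean) and an OLS regression on the
    numeric sampling date D (direction = slope sign).  P-values are
    unadjusted by default, mirroring a per-taxon screening analysis;
    ``adjust="bh"`` applies Benjamini-Hochberg within each factor.
    """
    meta = meta.reindex(m.index)
    values = m.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    rel = np.divide(values, sums, out=np.zeros_like(values), where=sums > 0)

    present = rel.sum(axis=0) > 0
    skipped = list(m.columns[~present])
    if skipped:
        log.info("taxa absent from all samples skipped: %s", skipped)
    rel = rel[:, present]
    taxa = list(m.columns[present])
    n = rel.shape[0]

    # --- forest: one-way ANOVA, vectorized over taxa
    flevels = sorted(meta["F"].astype(str).unique())
    groups = [rel[(meta["F"].astype(str) == lv).to_numpy()] for lv in flevels]
    grand = rel.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b, df_w = len(flevels) - 1, n - len(flevels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    p_forest = np.where(np.isfinite(f_stat), f_dist.sf(f_stat, df_b, df_w), 1.0)
    p_forest = np.where(ss_between + ss_within == 0, 1.0, p_forest)  # constant taxon
    means = np.stack([g.mean(axis=0) for g in groups])
    direction_f = [flevels[i] for i in means.argmax(axis=0)]

    # --- date: OLS slope on numeric day-of-year, vectorized
    x = meta["D"].to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    slope = rel.T @ xc / sxx
    fitted = np.outer(xc, slope) + rel.mean(axis=0)
    resid = rel - fitted
    df_t = n - 2
    sigma2 = (resid**2).sum(axis=0) / df_t
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = slope / np.sqrt(sigma2 / sxx)
    p_date = np.where(np.isfinite(t_stat), 2 * t_dist.sf(np.abs(t_stat), df_t), 1.0)

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_forest = multipletests(p_forest, method="fdr_bh")[1]
        p_date = multipletests(p_date, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = []
    for i, taxon in enumerate(taxa):
        out.append(
            {
                "taxon": taxon,
                "factor": "F",
                "direction": direction_f[i],
                "p": float(p_forest[i]),
                "significant": bool(p_forest[i] < alpha),
            }
        )
        out.append(
            {
                "taxon": taxon,
                "factor": "D",
                "direction": "+" if slope[i] > 0 else "-",
                "p": float(p_date[i]),
                "significant": bool(p_date[i] < alpha),
            }
        )
    return pd.DataFrame(out)
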