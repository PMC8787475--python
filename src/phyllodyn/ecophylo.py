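"""Ecophylogenetic community structure: MNTD and SES(MNTD).

A community is phylogenetically clustered when its taxa are more closely
related than expected under stochastic assembly.  The statistic is the mean
nearest taxon distance (MNTD): the average, over taxa present in a sample, of
the patristic distance to the nearest co-occurring taxon.  The standardized
effect size SES(MNTD) compares the observed value to a null distribution
obtained by drawing the same number of taxa uniformly (without replacement)
from the pool of taxa observed across all samples; negative SES indicates
clustering.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = ["cophenetic_distances", "mntd", "ses_mntd", "ses_anova"]

log = logging.getLogger(__name__)


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (sum of branch lengths) distance between every pair of tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def mntd(sample_taxa, d: pd.DataFrame) -> float:
    """Mean distance from each present taxon to its nearest co-occurring taxon.

    Presence-based (unweighted).  Undefined for fewer than 2 taxa.
    """
    taxa = sorted(set(sample_taxa))
    if len(taxa) < 2:
        raise ValueError("MNTD needs at least 2 taxa")
    missing = [t for t in taxa if t not in d.index]
    if missing:
        raise KeyError(f"taxa not in distance matrix: {missing}")
    sub = d.loc[taxa, taxa].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mntd_draws(dm: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """MNTD for each row of ``draws`` (index matrix into ``dm``), vectorized."""
    sub = dm[draws[:, :, None], draws[:, None, :]]
    k = draws.shape[1]
    sub[:, np.arange(k), np.arange(k)] = np.inf
    return sub.min(axis=2).mean(axis=1)


def ses_mntd(
    m: pd.DataFrame,
    d: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """SES(MNTD) per sample under a richness-preserving pool null.

    The taxon pool is every taxon observed in at least one sample.  For each
    sample with richness k, ``n_null`` random draws of k pool taxa (uniform,
    without replacement) give the null mean and SD; SES = (obs - null mean) /
    null SD, with a two-sided rank p-value.  Samples with fewer than 2 taxa,
    or whose null is degenerate (sample = entire pool, null SD = 0), are
    reported with missing SES and flagged.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    presence = m.to_numpy(dtype=float) > 0
    pool = list(m.columns[presence.any(axis=0)])
    missing = [t for t in pool if t not in d.index]
    if missing:
        raise KeyError(f"taxa not in distance matrix: {missing}")
    dm = d.loc[pool, pool].to_numpy(dtype=float)
    pool_idx = {t: i for i, t in enumerate(pool)}
    npool = len(pool)

    rows = []
    for s, sample in enumerate(m.index):
        taxa = [t for t in m.columns[presence[s]]]
        k = len(taxa)
        if k < 2:
            log.info("sample %s has fewer than 2 taxa; SES undefined", sample)
            rows.append({"sample": sample, "richness": k})
            continue
        obs = mntd(taxa, d)
        if k >= npool:
            log.info("sample %s contains the whole pool; null degenerate", sample)
            rows.append({"sample": sample, "richness": k, "mntd_obs": obs, "degenerate": True})
            continue
        # k uniform draws without replacement per null replicate
        gumbel = rng.random((n_null, npool))
        draws = np.argpartition(gumbel, k, axis=1)[:, :k]
        null = _mntd_draws(dm, draws)
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            rows.append({"sample": sample, "richness": k, "mntd_obs": obs, "degenerate": True})
            continue
        ses = (obs - mu) / sd
        lower = (1 + int((null <= obs).sum())) / (n_null + 1)
        upper = (1 + int((null >= obs).sum())) / (n_null + 1)
        p = min(1.0, 2 * min(lower, upper))
        rows.append(
            {
                "sample": sample,
                "richness": k,
                "mntd_obs": obs,
                "null_mean": mu,
                "null_sd": sd,
                "ses": ses,
                "p": p,
                "n_null": n_null,
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def ses_anova(
    ses: pd.DataFrame,
    meta: pd.DataFrame,
    factors: tuple[str, ...] = ("H", "F", "D"),
) -> pd.DataFrame:
    """Sequential ANOVA of SES(MNTD) on environmental factors.

    Factors are treated as categorical; single-level factors are skipped with
    a notice.  Returns the ANOVA table with F statistics and p-values.
    """
    data = ses.join(meta, how="inner").dropna(subset=["ses"])
    usable = []
    for f in factors:
        if data[f].nunique() < 2:
            log.info("factor %s has a single level; skipped", f)
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no factor with at least 2 levels")
    rhs = " + ".join(f"C(Q('{f}'))" for f in usable)
    fit = ols(f"ses ~ {rhs}", data=data).fit()
    table = anova_lm(fit, typ=1)
    table.index = [*usable, "Residual"]
    if np.isclose(data["ses"].var(ddof=0), 0):
        table["F"] = table["F"].fillna(0.0)
        table.loc[usable, "F"] = 0.0
    return table
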