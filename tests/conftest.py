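import dendropy
import numpy as np
import pandas as pd
import pytest

from phyllodyn import synthetic_data as sd


def tree_from_newick(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick")


@pytest.fixture(scope="session")
def small_sim():
    """A 40-tip, 4-clade tree with its planted clade map and isolate table."""
    cfg = sd.SimConfig(seed=11, n_tips=40, n_clades=4)
    tree, clades = sd.simulate_tree(cfg)
    iso = sd.simulate_isolates(tree, clades, sd.PlantedEffects(), cfg)
    return cfg, tree, clades, iso


@pytest.fixture(scope="session")
def community_bundle():
    """Zero-effect community matrix + metadata (exchangeable samples)."""
    cfg = sd.SimConfig(seed=21)
    counts, meta = sd.simulate_communities(sd.PlantedEffects(), cfg)
    return counts, meta


def brute_force_permanova(d: np.ndarray, meta: pd.DataFrame, terms):
    """Independent sequential PERMANOVA oracle via explicit hat matrices.

    Uses pseudo-inverse projections on raw dummy matrices (no shared code
    with the implementation's orthonormal-basis path).
    """
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j

    def hat(x):
        return x @ np.linalg.pinv(x.T @ x) @ x.T

    x = np.ones((n, 1))
    prev_tr = float(np.trace(hat(x) @ g))
    prev_rank = 1
    rows = []
    for term in terms:
        cols = term.split(":")
        combined = meta[cols].astype(str).agg(":".join, axis=1)
        dummies = pd.get_dummies(combined).to_numpy(dtype=float)
        x = np.hstack([x, dummies])
        h = hat(x)
        tr = float(np.trace(h @ g))
        rank = int(np.linalg.matrix_rank(x))
        rows.append({"term": term, "SS": tr - prev_tr, "df": rank - prev_rank})
        prev_tr, prev_rank = tr, rank
    ss_total = float(np.trace(g))
    ss_res = ss_total - prev_tr
    df_res = n - prev_rank
    out = pd.DataFrame(rows).set_index("term")
    out["R2"] = out["SS"] / ss_total
    out["F"] = (out["SS"] / out["df"]) / (ss_res / df_res)
    out.attrs["ss_res"] = ss_res
    out.attrs["df_res"] = df_res
    out.attrs["ss_total"] = ss_total
    return out
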