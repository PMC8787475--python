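"""Similarity-scaled ultrametric trees, taxon slicing, and node-trait tests.

Isolate phylogenies are rescaled so that node heights are pairwise nucleotide
similarities (PS): tips sit at PS = 1 and the root at the smallest mean
similarity.  Cutting the tree at a PS threshold partitions isolates into
discrete taxa; scanning thresholds gives a depth-resolved picture of how much
community variance each environmental factor explains.  Binary isolate traits
(forest of origin, temperature of isolation) are tested for association with
individual nodes by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "pairwise_similarity",
    "read_alignment_fasta",
    "collapse_low_support",
    "ultrametricize",
    "slice_taxa",
    "node_factor_test",
    "TaxonPartition",
    "check_ultrametric",
    "node_support",
]

log = logging.getLogger(__name__)

_UNAMBIGUOUS = frozenset(b"ACGTacgt")


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def pairwise_similarity(alignment: dict[str, str]) -> pd.DataFrame:
    """Pairwise nucleotide similarity from an alignment.

    PS(i, j) = matching sites / comparable sites, where a site is comparable
    only if both sequences carry an unambiguous base (A, C, G or T) there;
    gaps and ambiguity codes are excluded pairwise.

    Raises
    ------
    ValueError
        If sequences have unequal lengths, fewer than two sequences are
        given, or a pair shares no comparable site.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("pairwise similarity needs at least two sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must have equal length, got lengths {sorted(lengths)}")
    seqs = np.array([list(s.upper().encode()) for s in alignment.values()], dtype=np.uint8)
    valid = np.isin(seqs, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(labels)
    ps = np.ones((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            j = i + 1 + int(np.argmax(comparable == 0))
            raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
        matches = (both & (seqs[i] == seqs[i + 1 :])).sum(axis=1)
        ps[i, i + 1 :] = ps[i + 1 :, i] = matches / comparable
    return pd.DataFrame(ps, index=labels, columns=labels)


def node_support(node: dendropy.Node) -> float | None:
    """Support value of an internal node, from its label if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def collapse_low_support(tree: dendropy.Tree, min_support: float = 30.0) -> dendropy.Tree:
    """Collapse internal nodes whose support is below ``min_support`` percent.

    Supports are read from internal-node labels (the common Newick dialect).
    Nodes without a numeric label are kept.  The tip set is unchanged; the
    returned tree is a copy.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None and sup < min_support:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def ultrametricize(tree: dendropy.Tree, ps: pd.DataFrame) -> dendropy.Tree:
    """Rescale a tree so node heights are mean pairwise similarities.

    Each internal node's raw height is the mean PS over tip pairs whose most
    recent common ancestor is that node (pairs drawn from different child
    subtrees).  Heights are then clamped top-down in a postorder pass so that
    no node sits above any of its children (monotonicity); tips are at height
    1.  Edge lengths become height differences, so the output is ultrametric
    on the PS scale and patristic distance between tips i, j equals
    ``2 * (1 - PS_height(MRCA))``.
    """
    out = tree.clone(depth=1)
    tips = [leaf.taxon.label for leaf in out.leaf_node_iter()]
    missing = [t for t in tips if t not in ps.index]
    if missing:
        raise ValueError(f"tips missing from similarity matrix: {missing}")
    psm = ps.loc[tips, tips].to_numpy()
    idx = {t: i for i, t in enumerate(tips)}

    for node in out.postorder_node_iter():
        if node.is_leaf():
            node.ps_height = 1.0
            node._tipidx = [idx[node.taxon.label]]
            continue
        children = node.child_nodes()
        groups = [c._tipidx for c in children]
        total = 0.0
        count = 0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                block = psm[np.ix_(groups[a], groups[b])]
                total += block.sum()
                count += block.size
        raw = total / count
        node.ps_height = min(raw, min(c.ps_height for c in children))
        node._tipidx = [i for g in groups for i in g]

    for node in out.preorder_node_iter():
        del node._tipidx
        if node.parent_node is not None:
            node.edge.length = node.ps_height - node.parent_node.ps_height
    out.seed_node.edge.length = None
    return out


def check_ultrametric(utree: dendropy.Tree, tol: float = 1e-9) -> bool:
    """True if all tips are equidistant from the root (within ``tol``)."""
    depths = []
    for leaf in utree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return (max(depths) - min(depths)) < tol


@dataclass
class TaxonPartition:
    """A slicing of an ultrametric tree into discrete taxa at one threshold."""

    threshold: float
    assignments: dict[str, str] = field(repr=False)

    @property
    def n_taxa(self) -> int:
        return len(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tip": list(self.assignments), "taxon": list(self.assignments.values())}
        )


def slice_taxa(utree: dendropy.Tree, threshold: float) -> TaxonPartition:
    """Cut a PS-scaled ultrametric tree into taxa at a similarity threshold.

    Taxa are the maximal clades whose subtending node height is at least the
    threshold; a tip whose parent edge crosses the threshold becomes a
    singleton taxon.  Thresholds range from the root height (one taxon) to
    1.0 (every distinct tip its own taxon).
    """
    if threshold > 1.0:
        raise ValueError(f"threshold {threshold} above the similarity scale maximum of 1")
    root_h = utree.seed_node.ps_height
    if threshold < root_h - 1e-12:
        raise ValueError(f"threshold {threshold} below the root height {root_h:.6g}")

    assignments: dict[str, str] = {}
    counter = 0

    def assign_clade(node) -> None:
        nonlocal counter
        counter += 1
        taxon = f"tx{counter:04d}"
        for leaf in node.leaf_iter():
            assignments[leaf.taxon.label] = taxon

    def walk(node) -> None:
        if node.is_leaf() or node.ps_height >= threshold:
            assign_clade(node)
        else:
            for child in node.child_nodes():
                walk(child)

    walk(utree.seed_node)
    return TaxonPartition(threshold=threshold, assignments=assignments)


def node_factor_test(
    utree: dendropy.Tree,
    meta: pd.DataFrame,
    factor: str,
    n_perm: int = 100_000,
    seed: int | None = None,
    method: str = "permutation",
    min_support: float | None = None,
) -> pd.DataFrame:
    """Test every internal node for association with a binary isolate trait.

    For a node holding ``n`` isolates, the statistic is the count of the
    node's majority trait level.  The null permutes trait labels uniformly
    across all isolates; per node this induces a hypergeometric distribution
    for the level count, which is either sampled (``method='permutation'``,
    with the +1 finite-sample correction so p > 0) or enumerated exactly
    (``method='exact'``).  P-values are Bonferroni-adjusted over all tested
    nodes and flagged at 0.05 / 0.01 / 0.001.

    Parameters
    ----------
    utree : tree whose tips are isolate IDs present in ``meta``.
    meta : isolate metadata indexed by isolate ID (or with an ``isolate``
        column), holding the ``factor`` column with exactly two levels.
    factor : column to test, e.g. ``"F"`` or ``"T_I"``.
    min_support : if given, nodes with recorded support below this are skipped.
    """
    if "isolate" in meta.columns:
        meta = meta.set_index("isolate")
    labels = meta[factor]
    levels = sorted(labels.unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {levels}")
    if method not in {"permutation", "exact"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "permutation" and seed is None:
        raise ValueError("seed is required for the permutation method")

    N = len(labels)
    level_counts = labels.value_counts()
    rng = np.random.default_rng(seed)

    rows = []
    node_id = 0
    for node in utree.preorder_internal_node_iter():
        node_id += 1
        if min_support is not None:
            sup = node_support(node)
            if sup is not None and sup < min_support:
                continue
        tips = [leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon.label in labels.index]
        n = len(tips)
        if n < 2:
            log.info("node %d skipped: fewer than 2 isolates", node_id)
            continue
        if n == N and node.parent_node is None:
            # the root contains everything; the statistic is non-informative
            pass
        counts = labels.loc[tips].value_counts()
        obs_level = max(levels, key=lambda lv: (counts.get(lv, 0), str(lv)))
        obs = int(counts.get(obs_level, 0))
        K = int(level_counts[obs_level])
        if method == "exact":
            p = float(hypergeom.sf(obs - 1, N, K, n))
        else:
            draws = rng.hypergeometric(K, N - K, n, size=n_perm)
            p = (1 + int((draws >= obs).sum())) / (n_perm + 1)
        rows.append(
            {
                "node": node_id,
                "n_isolates": n,
                "level": obs_level,
                "statistic": obs,
                "ps_height": getattr(node, "ps_height", np.nan),
                "p": p,
                "tips": ";".join(sorted(tips)),
            }
        )

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    m = len(result)
    result["p_bonferroni"] = np.minimum(1.0, result["p"] * m)
    result["flag"] = [
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        for p in result["p_bonferroni"]
    ]
    result["factor"] = factor
    result["n_perm"] = n_perm if method == "permutation" else 0
    return result
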