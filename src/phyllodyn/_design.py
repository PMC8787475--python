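"""Sequential (Type-I) design-matrix machinery shared by PERMANOVA and ANOVA.

Terms are strings naming metadata columns, with ``":"`` denoting an
interaction (``"F:H"`` is the crossing of factors F and H).  Each term is
orthogonalized against everything fitted before it, so sums of squares are
order-dependent, as in a classical sequential ANOVA table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SequentialDesign", "build_sequential_design", "term_dummies"]

_RANK_TOL = 1e-9


def term_dummies(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Indicator columns for a term; interactions cross the factor levels."""
    cols = term.split(":")
    missing = [c for c in cols if c not in meta.columns]
    if missing:
        raise KeyError(f"term {term!r} references unknown columns {missing}")
    if len(cols) == 1:
        combined = meta[cols[0]].astype(str)
    else:
        combined = meta[cols].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(combined).to_numpy(dtype=float)


@dataclass
class SequentialDesign:
    """Orthonormal bases for a sequence of model terms.

    ``basis`` has one orthonormal column per fitted degree of freedom (the
    intercept excluded); ``slices[i]`` selects the columns contributed by
    ``terms[i]``; ``df[i]`` is that term's degrees of freedom (0 when the term
    is aliased by earlier terms).
    """

    terms: list[str]
    basis: np.ndarray
    slices: list[slice]
    df: list[int]
    n: int

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - 1 - self.rank


def build_sequential_design(meta: pd.DataFrame, terms: list[str]) -> SequentialDesign:
    n = len(meta)
    fitted = np.full((n, 1), 1.0 / np.sqrt(n))  # intercept direction
    blocks: list[np.ndarray] = []
    slices: list[slice] = []
    dfs: list[int] = []
    start = 0
    for term in terms:
        X = term_dummies(meta, term)
        # residualize against everything fitted so far (incl. intercept)
        R = X - fitted @ (fitted.T @ X)
        u, s, _ = np.linalg.svd(R, full_matrices=False)
        keep = s > _RANK_TOL * max(1.0, s[0] if s.size else 1.0)
        U_new = u[:, keep]
        df = U_new.shape[1]
        fitted = np.hstack([fitted, U_new])
        blocks.append(U_new)
        slices.append(slice(start, start + df))
        dfs.append(df)
        start += df
    basis = np.hstack(blocks) if blocks else np.empty((n, 0))
    return SequentialDesign(terms=list(terms), basis=basis, slices=slices, df=dfs, n=n)
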