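"""Lightweight design-matrix construction for the weighting and outcome models.

Builds dense float64 matrices with an explicit intercept, treatment-coded
categorical expansion (first category as reference) and automatic removal
of constant columns (recorded, so e.g. a stratified run that makes a
covariate degenerate is handled transparently rather than failing on rank
deficiency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "DesignMatrix"]


class DesignMatrix:
    def __init__(self, X: np.ndarray, names: list[str], dropped: list[str]):
        self.X = X
        self.names = names
        self.dropped = dropped

    @property
    def shape(self):
        return self.X.shape


def _expand(table: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    col = table[term]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        cats = (
            list(col.cat.categories)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(pd.unique(col.dropna()))
        )
        cols, names = [], []
        for cat in cats[1:]:  # first level is the reference
            cols.append((col == cat).to_numpy(dtype=np.float64))
            names.append(f"{term}[{cat}]")
        if not cols:
            return np.empty((len(table), 0)), []
        return np.column_stack(cols), names
    return col.to_numpy(dtype=np.float64)[:, None], [term]


def build_design(
    table: pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    *,
    intercept: bool = True,
    drop_constant: bool = True,
) -> DesignMatrix:
    """Assemble a design matrix from named columns of ``table``.

    Categorical and object columns expand to indicator columns against
    their first level.  Constant columns (other than the intercept) are
    dropped and recorded in ``dropped``.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        blocks.append(np.ones((len(table), 1)))
        names.append("const")
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"design term {term!r} not in table")
        block, bnames = _expand(table, term)
        blocks.append(block)
        names.extend(bnames)
    X = np.hstack(blocks) if blocks else np.empty((len(table), 0))
    dropped: list[str] = []
    if drop_constant and X.shape[0] > 0:
        keep = np.ones(X.shape[1], dtype=bool)
        for j in range(1 if intercept else 0, X.shape[1]):
            colj = X[:, j]
            if np.all(colj == colj[0]):
                keep[j] = False
                dropped.append(names[j])
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return DesignMatrix(np.ascontiguousarray(X), names, dropped)
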