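"""Quadratic and cubic interaction designs and index decoding.

The quadratic expansion maps base columns ``(a_1, ..., a_k)`` to

    (a_1, ..., a_k, a_11, ..., a_1k, a_22, ..., a_2k, ..., a_kk)

i.e. the linear terms followed, for each ``i``, by the block of products
``a_i * a_j`` with ``j >= i``.  The cubic expansion appends, for each ``i``,
the block of triple products ``a_i * a_j * a_l`` over ``i <= j <= l`` in
ascending ``(j, l)`` order.  ``find_int`` inverts the flattened 1-based
column index back to the tuple of base-variable indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = ["ExpandedDesign", "quadr", "cub", "find_int", "n_expanded_columns"]


def n_expanded_columns(k: int, order: int) -> int:
    """Closed-form column count: k + k(k+1)/2 (+ C(k+2,3) for cubic)."""
    if order == 2:
        return k + k * (k + 1) // 2
    if order == 3:
        return k + k * (k + 1) // 2 + comb(k + 2, 3)
    raise ValueError("order must be 2 or 3")


def _index_tuples(k: int, order: int) -> list:
    tuples = [(i,) for i in range(1, k + 1)]
    for i in range(1, k + 1):
        tuples.extend((i, j) for j in range(i, k + 1))
    if order == 3:
        for i in range(1, k + 1):
            tuples.extend((i, j, l) for j in range(i, k + 1) for l in range(j, k + 1))
    return tuples


@dataclass
class ExpandedDesign:
    """An interaction-expanded numeric design.

    ``index_map[j]`` (0-based position) is the sorted tuple of 1-based base
    indices whose elementwise product forms column ``j``.
    """

    base_count: int
    order: int
    columns: np.ndarray
    index_map: tuple
    names: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, columns=list(self.names))


def _expand(base, order: int) -> ExpandedDesign:
    if isinstance(base, pd.DataFrame):
        base_names = [str(c) for c in base.columns]
        mat = base.to_numpy()
    else:
        mat = np.asarray(base)
        base_names = [f"x{i}" for i in range(1, mat.shape[1] + 1)]
    if mat.ndim != 2:
        raise ValueError("base must be a 2-D matrix")
    if not np.issubdtype(mat.dtype, np.number):
        raise ValueError("interaction expansion is not well-defined for non-numeric variables")
    mat = mat.astype(float)
    k = mat.shape[1]
    tuples = _index_tuples(k, order)
    cols = np.empty((mat.shape[0], len(tuples)))
    names = []
    for j, t in enumerate(tuples):
        cols[:, j] = np.prod(mat[:, [i - 1 for i in t]], axis=1)
        names.append("*".join(base_names[i - 1] for i in t))
    return ExpandedDesign(k, order, cols, tuple(tuples), tuple(names))


def quadr(base) -> ExpandedDesign:
    """Quadratic expansion: linear terms plus all squares and pairwise products."""
    return _expand(base, 2)


def cub(base) -> ExpandedDesign:
    """Cubic expansion: the quadratic design plus all degree-3 monomials."""
    return _expand(base, 3)


def find_int(ind: int, k: int, order: int = 2) -> tuple:
    """Decode a flattened 1-based expanded-column index to base indices.

    ``find_int(6, 3)`` → ``(1, 3)``: the sixth quadratic column over three
    base variables is the interaction of the first and the third.
    """
    total = n_expanded_columns(k, order)
    if not 1 <= ind <= total:
        raise IndexError(f"index {ind} out of range 1..{total} for k={k}, order={order}")
    return _index_tuples(k, order)[ind - 1]
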