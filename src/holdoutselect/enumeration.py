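"""Lazy enumeration of admissible predictor subsets.

Subsets are streamed in lexicographic order of their (0-based) index tuples
via depth-first search, pruning on the total-weight bound (weights are
positive, so no superset of an overweight subset can be admissible) and on
the pairwise-correlation bound (a subset containing an over-correlated pair
never loses it by growing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np

from .data_model import Constraints

__all__ = ["ModelSubset", "enumerate_subsets", "passes_correlation", "count_subsets"]


@dataclass(frozen=True)
class ModelSubset:
    """A candidate model: sorted 0-based predictor positions and their total weight."""

    indices: tuple
    weight: int

    def __len__(self):
        return len(self.indices)


def passes_correlation(subset, correlation: np.ndarray, c: float) -> bool:
    """True iff every pairwise |correlation| among subset members is <= c.

    The bound is inclusive; ``c = 1`` accepts everything.
    """
    if c >= 1.0:
        return True
    idx = list(subset.indices if isinstance(subset, ModelSubset) else subset)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if abs(correlation[idx[a], idx[b]]) > c:
                return False
    return True


def count_subsets(n: int, w: int) -> int:
    """Number of non-empty subsets of at most w out of n unit-weight columns:
    sum_{i=1..w} C(n, i), exact."""
    if not 0 <= w <= n:
        raise ValueError("need 0 <= w <= n")
    return sum(comb(n, i) for i in range(1, w + 1))


def enumerate_subsets(weights, constraints: Constraints, max_total_weight: int,
                      correlation: np.ndarray | None = None):
    """Stream every admissible ModelSubset.

    Emits exactly the subsets S with ``forced ⊆ S``,
    ``min_vars <= |S| <= max_vars``,
    ``weight(S) <= min(max_total_weight, constraints.max_weight)`` and (when a
    correlation matrix is given) all pairwise |r| <= max_correlation, in
    lexicographic order of index tuples, without duplicates.  Columns with
    weight 0 (constants) are never candidates.
    """
    weights = np.asarray(weights, dtype=int)
    n = len(weights)
    forced = frozenset(constraints.forced)
    if any(j < 0 or j >= n for j in forced):
        raise ValueError("forced indices out of range")
    bound = max_total_weight
    if constraints.max_weight is not None:
        bound = min(bound, constraints.max_weight)
    max_vars = constraints.max_vars if constraints.max_vars is not None else n
    min_vars = max(constraints.min_vars, 1)

    forced_weight = int(weights[list(forced)].sum()) if forced else 0
    if forced and (forced_weight > bound or any(weights[j] == 0 for j in forced)):
        warnings.warn("forced set is itself inadmissible; no candidate models")
        return

    usable = [j for j in range(n) if weights[j] > 0]
    check_corr = correlation is not None and constraints.max_correlation < 1.0
    c = constraints.max_correlation

    def extend(start_pos, current, cur_weight):
        for pos in range(start_pos, len(usable)):
            j = usable[pos]
            w = cur_weight + weights[j]
            if w > bound:
                continue
            if check_corr and any(abs(correlation[j, m]) > c for m in current):
                continue
            current.append(j)
            if len(current) >= min_vars and forced.issubset(current):
                yield ModelSubset(tuple(current), int(w))
            if len(current) < max_vars:
                yield from extend(pos + 1, current, w)
            current.pop()

    yield from extend(0, [], 0)
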