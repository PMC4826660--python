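"""Fisher-Jenks natural-breaks classification of area rates.

Partitions a numeric series into k classes of contiguous sorted values so
that the within-class sum of squared deviations from class means (SSD) is
globally minimal — the classing used for choropleth legends of area rates.
The optimum is found by exact dynamic programming over the sorted values with
prefix-sum cost evaluation (instances here are a few dozen areas, so the
heuristic reallocation variant is unnecessary); ties between equally good
partitions are broken toward the lexicographically smallest boundary-index
vector for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BreaksResult:
    """An optimal k-class partition of a sorted value set."""

    k: int
    boundaries: tuple[float, ...]  # upper bound (max value) of each class
    assignments: tuple[int, ...]  # class index per input value, input order
    within_ssd: float
    total_ssd: float

    @property
    def gvf(self) -> float:
        """Goodness of variance fit, 1 - within/total SSD (0 for k=1)."""
        if self.total_ssd == 0:
            return 1.0
        return 1.0 - self.within_ssd / self.total_ssd


def _segment_cost(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """SSD of sorted values with indices [i, j) around their own mean."""
    n = j - i
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    return sq - s * s / n


def jenks_breaks(values: list[float] | np.ndarray, k: int) -> BreaksResult:
    """Exact natural-breaks optimization of ``values`` into ``k`` classes.

    Requires ``1 <= k <=`` the number of distinct values so every class is
    non-empty and boundaries are strictly increasing.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot classify an empty value list")
    if not np.isfinite(vals).all():
        raise ValueError("values must be finite")
    n_distinct = len(np.unique(vals))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} outside [1, {n_distinct} distinct values]")

    order = np.argsort(vals, kind="stable")
    x = vals[order]
    n = len(x)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])

    # dp[c][j]: minimal SSD partitioning x[:j] into c classes; back[c][j]: the
    # start index of the last class (smallest among ties -> lexicographically
    # smallest boundary vector overall, scanning split points ascending).
    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            for i in range(c - 1, j):
                if dp[c - 1][i] == INF:
                    continue
                cost = dp[c - 1][i] + _segment_cost(prefix, prefix_sq, i, j)
                if cost < best - 1e-12:
                    best, best_i = cost, i
            dp[c][j], back[c][j] = best, best_i

    # Recover class extents; force class changes only at distinct-value edges
    # by construction of the optimum (equal values always group together).
    cuts = []
    j = n
    for c in range(k, 0, -1):
        i = back[c][j]
        cuts.append((i, j))
        j = i
    cuts.reverse()

    sorted_assign = np.empty(n, dtype=int)
    boundaries = []
    for cls, (i, j) in enumerate(cuts):
        sorted_assign[i:j] = cls
        boundaries.append(float(x[j - 1]))

    assignments = np.empty(n, dtype=int)
    assignments[order] = sorted_assign
    total_ssd = _segment_cost(prefix, prefix_sq, 0, n)
    return BreaksResult(
        k=k,
        boundaries=tuple(boundaries),
        assignments=tuple(int(a) for a in assignments),
        within_ssd=float(dp[k][n]),
        total_ssd=float(total_ssd),
    )


def classify_areas(rates: pd.Series, k: int) -> tuple[pd.DataFrame, list[str]]:
    """Classify per-area rates into k natural-breaks classes.

    Returns (table with area_id, rate, class_index, class_interval; legend).
    Legend intervals are half-open [lower, upper) except the last, closed.
    """
    result = jenks_breaks(rates.to_numpy(), k)
    lowers = [float(np.min(rates))] + [b for b in result.boundaries[:-1]]
    legend = []
    for cls in range(k):
        lo = lowers[cls] if cls == 0 else result.boundaries[cls - 1]
        hi = result.boundaries[cls]
        if cls < k - 1:
            legend.append(f"[{lo:.1f}, {hi:.1f})")
        else:
            legend.append(f"[{lo:.1f}, {hi:.1f}]")
    table = pd.DataFrame(
        {
            "area_id": rates.index,
            "rate": rates.to_numpy(),
            "class_index": result.assignments,
            "class_interval": [legend[c] for c in result.assignments],
        }
    )
    return table, legend
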