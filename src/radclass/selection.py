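"""Per-cluster representative screening.

Each modelling strategy keeps at most one feature per cluster, screened on the
training split only.  The all-subsets regression route keeps the feature with
the largest absolute point-biserial correlation with the binary outcome,
provided it explains more than 5% of outcome variance (r^2 > 0.05).  The
recursive-partitioning route keeps the feature with the smallest
Kruskal-Wallis p-value, provided p < 0.1; the test accepts any number of
outcome levels (two-level outcomes give the 1-df test).  Ties are broken by
lexicographic feature name so results never depend on column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from radclass.preprocessing import ClusterAssignment

APS = "APS"
PARTITION = "PARTITION"
PREVALENCE = "PREVALENCE"


def point_biserial(x: np.ndarray, y01: np.ndarray) -> float:
    """Pearson correlation of a numeric feature with a 0/1-coded outcome.

    Returns NaN (screened out upstream) when the feature is constant or only
    one class is present.
    """
    x = np.asarray(x, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    if np.std(x) == 0 or np.std(y01) == 0:
        return float("nan")
    return float(np.corrcoef(x, y01)[0, 1])


def kruskal_wallis(x: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    All-tied samples are a degenerate case: H = 0, p = 1.
    """
    g = np.asarray(g)
    groups = [np.asarray(x, dtype=float)[g == level] for level in np.unique(g)]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if np.all(np.asarray(x) == np.asarray(x)[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class SelectionResult:
    """Chosen representatives and the per-feature screening statistics."""

    method: str                                   # APS | PARTITION
    chosen: dict[int, str] = field(default_factory=dict)   # cluster -> feature
    screen_stat: dict[str, float] = field(default_factory=dict)
    # APS: screen_stat holds the point-biserial r; PARTITION: the KW p-value

    @property
    def features(self) -> list[str]:
        return sorted(self.chosen.values())


def select_aps_representatives(train: pd.DataFrame, y: np.ndarray,
                               clusters: ClusterAssignment,
                               r2_threshold: float = 0.05) -> SelectionResult:
    """One representative per cluster by largest |point-biserial r|, kept only
    if r^2 exceeds ``r2_threshold``; clusters with no qualifying feature
    contribute nothing."""
    y01 = _binary_code(y)
    result = SelectionResult(method=APS)
    for label in clusters.labels:
        best_name, best_abs = None, -np.inf
        for name in sorted(clusters.members(label)):
            r = point_biserial(train[name].to_numpy(), y01)
            result.screen_stat[name] = r
            if np.isnan(r):
                continue
            if abs(r) > best_abs:   # strict: first (lexicographic) wins ties
                best_name, best_abs = name, abs(r)
        if best_name is not None and best_abs ** 2 > r2_threshold:
            result.chosen[label] = best_name
    return result


def select_partition_representatives(train: pd.DataFrame, y: np.ndarray,
                                     clusters: ClusterAssignment,
                                     p_threshold: float = 0.1) -> SelectionResult:
    """One representative per cluster by smallest Kruskal-Wallis p-value, kept
    only if p is below ``p_threshold``; works for 2+ outcome levels."""
    y = np.asarray(y)
    result = SelectionResult(method=PARTITION)
    for label in clusters.labels:
        best_name, best_p = None, np.inf
        for name in sorted(clusters.members(label)):
            _, p = kruskal_wallis(train[name].to_numpy(), y)
            result.screen_stat[name] = p
            if p < best_p:          # strict: first (lexicographic) wins ties
                best_name, best_p = name, p
        if best_name is not None and best_p < p_threshold:
            result.chosen[label] = best_name
    return result


def _binary_code(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError(
            f"point-biserial screening needs a binary outcome, got {len(levels)} levels")
    return (y == levels[1]).astype(float)
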