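"""Feature QC, skew transforms, rank-based normalization, and clustering.

Order of operations in the pipeline: features missing on more than 20% of
participants and zero-variance features are removed; a data-independent skew
transform (log, or signed square root) is fitted on the training split for
features with mean/median ratio > 1.5 and reapplied unchanged to the test
split; a rank-based inverse-normal (ordered-quantile) normalization is used
only to compute the clustering distance; features are grouped by complete-
linkage hierarchical clustering on 1 - |Pearson r|, cut at 15 clusters per
modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata

from radclass.cohort import modality_of


class DataError(ValueError):
    """Raised when input data violate a pipeline precondition."""


@dataclass
class RemovalLog:
    missing: dict[str, float] = field(default_factory=dict)  # feature -> rate
    zero_variance: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return list(self.missing) + self.zero_variance


def qc_filter(table: pd.DataFrame, missing_threshold: float = 0.20,
              impute_median: bool = False) -> tuple[pd.DataFrame, RemovalLog]:
    """Remove features missing on more than ``missing_threshold`` of patients
    and features with no variability (a single distinct non-missing value).

    After filtering, any remaining missing value is a hard error naming the
    offending features — the pipeline assumes a complete post-QC table.  Pass
    ``impute_median=True`` to median-impute the stragglers instead (off by
    default; an escape hatch, not part of the reference procedure).
    """
    if table.shape[1] == 0:
        raise DataError("qc_filter received a table with no features")
    n = len(table)
    frac_missing = table.isna().sum() / n
    log = RemovalLog()
    log.missing = {f: float(r) for f, r in frac_missing.items()
                   if r > missing_threshold}
    kept = table.drop(columns=list(log.missing))
    nunique = kept.nunique(dropna=True)
    log.zero_variance = [f for f in kept.columns if nunique[f] <= 1]
    kept = kept.drop(columns=log.zero_variance)
    if kept.isna().any().any():
        offenders = kept.columns[kept.isna().any()].tolist()
        if impute_median:
            kept = kept.fillna(kept.median())
        else:
            raise DataError(
                "missing values remain after QC in features "
                f"{offenders[:10]}; remove them, raise the threshold, or pass "
                "impute_median=True")
    return kept, log


# ---------------------------------------------------------------------------
# Data-independent skew transforms


@dataclass(frozen=True)
class TransformSpec:
    """Per-feature transform fitted on a training split and reapplied as-is.

    kind 'log' requires all observed training values strictly positive;
    'signed_sqrt' is x -> sign(x) * sqrt(|x|); 'identity' otherwise.
    """

    kind: str                # identity | log | signed_sqrt
    mean_median_ratio: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return values
        if self.kind == "log":
            if np.any(values <= 0):
                raise DataError("log transform applied to non-positive values")
            return np.log(values)
        if self.kind == "signed_sqrt":
            return np.sign(values) * np.sqrt(np.abs(values))
        raise ValueError(f"unknown transform kind {self.kind!r}")


def fit_skew_transform(train_values: np.ndarray,
                       ratio_threshold: float = 1.5) -> TransformSpec:
    """Decide the transform from the training mean/median ratio.

    ratio <= threshold -> identity; ratio > threshold with strictly positive
    values -> natural log; otherwise -> signed square root.  A zero median
    leaves the ratio undefined: identity, with a warning.
    """
    x = np.asarray(train_values, dtype=float)
    if np.isnan(x).any():
        raise DataError("fit_skew_transform requires a complete vector")
    med = float(np.median(x))
    if med == 0.0:
        warnings.warn("median is zero; mean/median ratio undefined, "
                      "keeping identity transform", stacklevel=2)
        return TransformSpec("identity", np.nan)
    ratio = float(np.mean(x)) / med
    if ratio <= ratio_threshold:
        return TransformSpec("identity", ratio)
    if np.min(x) > 0:
        return TransformSpec("log", ratio)
    return TransformSpec("signed_sqrt", ratio)


def fit_transforms(train: pd.DataFrame,
                   ratio_threshold: float = 1.5) -> dict[str, TransformSpec]:
    return {f: fit_skew_transform(train[f].to_numpy(), ratio_threshold)
            for f in train.columns}


def apply_transforms(table: pd.DataFrame,
                     specs: dict[str, TransformSpec]) -> pd.DataFrame:
    out = {}
    for f in table.columns:
        spec = specs.get(f, TransformSpec("identity", np.nan))
        out[f] = spec.apply(table[f].to_numpy())
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Data-dependent normalization (used only for the clustering distance)


class RankNormalizer:
    """Rank-based inverse-normal (ordered-quantile) transform.

    Training value with rank r among n maps to ``Phi^-1((r - 0.5) / n)``; ties
    receive the mean of their ranks.  ``transform`` maps unseen values by
    monotone interpolation of the fitted value -> normal-score curve.  The
    normalized scale feeds the feature-clustering distance only; models are
    fitted on the data-independent transforms.
    """

    def fit(self, train_values: np.ndarray) -> "RankNormalizer":
        x = np.asarray(train_values, dtype=float)
        if np.isnan(x).any():
            raise DataError("RankNormalizer requires a complete vector")
        if np.all(x == x[0]):
            raise DataError("constant vector cannot be rank-normalized "
                            "(should have been removed by qc_filter)")
        n = len(x)
        self.scores_ = norm.ppf((rankdata(x, method="average") - 0.5) / n)
        order = np.argsort(x, kind="stable")
        self.x_sorted_ = x[order]
        self.s_sorted_ = self.scores_[order]
        return self

    def fit_transform(self, train_values: np.ndarray) -> np.ndarray:
        return self.fit(train_values).scores_

    def transform(self, values: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(values, dtype=float),
                         self.x_sorted_, self.s_sorted_)


def normalize_table(train: pd.DataFrame) -> pd.DataFrame:
    """Rank-inverse-normal normalize every column of a training table."""
    return pd.DataFrame(
        {f: RankNormalizer().fit_transform(train[f].to_numpy())
         for f in train.columns},
        index=train.index)


# ---------------------------------------------------------------------------
# Complete-linkage feature clustering


@dataclass
class ClusterAssignment:
    modality: str
    k: int
    member_of: dict[str, int]   # feature -> cluster label (1..k)

    def members(self, label: int) -> list[str]:
        return [f for f, c in self.member_of.items() if c == label]

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.member_of.values()))


def cluster_features(normalized_train: pd.DataFrame, modality: str,
                     k: int = 15) -> ClusterAssignment:
    """Group a modality's features into ``k`` clusters.

    Agglomerative clustering with complete linkage on the distance
    ``1 - |Pearson r|`` over training patients; the absolute value makes the
    grouping invariant to feature sign flips.  If the modality has fewer than
    ``k`` features, ``k`` is reduced to the feature count with a warning.
    """
    cols = [f for f in normalized_train.columns if modality_of(f) == modality]
    if not cols:
        raise DataError(f"no features tagged with modality {modality!r}")
    if len(cols) < k:
        warnings.warn(f"only {len(cols)} {modality} features; reducing k from "
                      f"{k} to {len(cols)}", stacklevel=2)
        k = len(cols)
    if len(cols) == 1:
        return ClusterAssignment(modality, 1, {cols[0]: 1})
    corr = np.corrcoef(normalized_train[cols].to_numpy(), rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    tree = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(tree, t=k, criterion="maxclust")
    return ClusterAssignment(modality, k, dict(zip(cols, (int(c) for c in flat))))
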