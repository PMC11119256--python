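"""The three model families fitted per cross-validation training set.

* All-possible-subsets (APS) logistic regression: every non-empty subset of
  the selected representatives is fitted; per subset the decision threshold
  is the train-ROC cut maximizing the Youden index (sensitivity +
  specificity - 1); the subset with the highest training Youden wins, ties
  going to fewer features then lexicographic subset order.
* Recursive partitioning: a seeded random forest ranks the representatives by
  permutation importance; depth-capped CART trees are grown on the top-m
  features for m = 1..k (max depth m, to limit over-fitting); the m with the
  largest training Cohen's kappa wins, ties to smaller m.
* Prevalence-only benchmark: test patients are randomly assigned classes at
  the training-set class frequencies — the chance-level reference.

A combined-modality model refits the chosen strategy on the union of the
CT-only and PET-only models' final feature sets (no re-screening).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier, export_text

from radclass.selection import APS, PARTITION

# ridge weight on the logistic coefficients: keeps perfectly separating
# subsets finite without materially moving the Youden-based selection
DEFAULT_RIDGE = 1e-6
MAX_APS_SUBSETS = 2 ** 20


class FallbackToPrevalence(Exception):
    """No feature passed screening: the caller should use the prevalence model."""


@dataclass
class APSModel:
    subset: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    threshold: float
    train_youden: float
    positive_class: object
    negative_class: object

    def describe(self) -> dict:
        return {
            "kind": "APS",
            "subset": list(self.subset),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "threshold": self.threshold,
            "train_youden": self.train_youden,
            "positive_class": str(self.positive_class),
        }


@dataclass
class PartitionModel:
    ordered_features: list[str]     # by decreasing random-forest importance
    m: int                          # features / maximum depth actually used
    tree: DecisionTreeClassifier
    train_kappa: float
    seed: int

    @property
    def used_features(self) -> list[str]:
        return self.ordered_features[: self.m]

    def describe(self) -> dict:
        return {
            "kind": "PARTITION",
            "ordered_features": self.ordered_features,
            "m": self.m,
            "train_kappa": self.train_kappa,
            "tree": export_text(self.tree, feature_names=self.used_features),
        }


@dataclass
class PrevalenceModel:
    class_probs: dict = field(default_factory=dict)

    def describe(self) -> dict:
        return {"kind": "PREVALENCE",
                "class_probs": {str(k): v for k, v in self.class_probs.items()}}


# ---------------------------------------------------------------------------
# APS logistic regression


def _youden_threshold(y01: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    """Train-ROC cut maximizing Youden; ties resolved to the lowest cut.

    Returns (threshold, youden at that threshold); a patient is called
    positive when probability >= threshold.
    """
    fpr, tpr, thresholds = roc_curve(y01, probs)
    j = tpr - fpr
    idx = np.flatnonzero(j == j.max())[-1]   # thresholds descend: last = lowest
    return float(min(thresholds[idx], 1.0)), float(j[idx])


def _fit_logistic(X: np.ndarray, y01: np.ndarray, ridge: float):
    model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y01)
    return model


def fit_aps(X_train: pd.DataFrame, y, positive_class,
            ridge: float = DEFAULT_RIDGE,
            max_subsets: int = MAX_APS_SUBSETS) -> APSModel:
    """Exhaustive subset search for the highest-training-Youden logistic model.

    Subsets are visited smallest-first in lexicographic order and a strictly
    larger Youden is required to displace the incumbent, which implements the
    tie-break (fewer features, then lexicographic order).
    """
    features = sorted(X_train.columns)
    if not features:
        raise FallbackToPrevalence("no selected features for APS")
    if 2 ** len(features) - 1 > max_subsets:
        raise ValueError(
            f"{len(features)} candidate features imply more than {max_subsets} "
            "subsets; refusing exhaustive enumeration")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2 or positive_class not in classes:
        raise ValueError("APS requires a binary outcome containing the positive class")
    negative_class = classes[classes != positive_class][0]
    y01 = (y == positive_class).astype(int)

    best = None
    best_youden = -np.inf
    for size in range(1, len(features) + 1):
        for subset in itertools.combinations(features, size):
            model = _fit_logistic(X_train[list(subset)].to_numpy(), y01, ridge)
            probs = model.predict_proba(X_train[list(subset)].to_numpy())[:, 1]
            threshold, youden = _youden_threshold(y01, probs)
            if youden > best_youden:
                best_youden = youden
                best = APSModel(
                    subset=subset,
                    coefficients=dict(zip(subset, model.coef_[0].tolist())),
                    intercept=float(model.intercept_[0]),
                    threshold=threshold,
                    train_youden=youden,
                    positive_class=positive_class,
                    negative_class=negative_class,
                )
    return best


def predict_aps(model: APSModel, X_test: pd.DataFrame):
    """Class labels and positive-class probabilities from the logistic form."""
    missing = [f for f in model.subset if f not in X_test.columns]
    if missing:
        raise ValueError(f"test table lacks model features {missing}")
    X = X_test[list(model.subset)].to_numpy(dtype=float)
    w = np.array([model.coefficients[f] for f in model.subset])
    eta = model.intercept + X @ w
    probs = 1.0 / (1.0 + np.exp(-eta))
    labels = np.where(probs >= model.threshold,
                      model.positive_class, model.negative_class)
    return labels, probs


# ---------------------------------------------------------------------------
# Recursive partitioning with random-forest importance ordering


def fit_partition(X_train: pd.DataFrame, y, seed: int,
                  n_trees: int = 500, min_samples_leaf: int = 5,
                  importance_repeats: int = 5) -> PartitionModel:
    """Random-forest permutation-importance ordering, then depth-capped CART.

    The forest (``n_trees`` trees, sqrt(k) features per split) only orders the
    candidates; the final classifier is the CART tree over the top-m features
    with max depth m whose training kappa is largest (ties to smaller m).
    """
    features = sorted(X_train.columns)
    if not features:
        raise FallbackToPrevalence("no selected features for partitioning")
    y = np.asarray(y)
    rf_seed, perm_seed, tree_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2 ** 31))
    X = X_train[features]
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=rf_seed, n_jobs=1)
    rf.fit(X, y)
    perm = permutation_importance(rf, X, y, n_repeats=importance_repeats,
                                  random_state=perm_seed, n_jobs=1)
    order = sorted(range(len(features)),
                   key=lambda i: (-perm.importances_mean[i], features[i]))
    ordered = [features[i] for i in order]

    from radclass.evaluation import cohen_kappa  # local import: avoids a cycle

    best_tree, best_m, best_kappa = None, 0, -np.inf
    for m in range(1, len(ordered) + 1):
        tree = DecisionTreeClassifier(max_depth=m,
                                      min_samples_leaf=min_samples_leaf,
                                      random_state=tree_seed)
        tree.fit(X_train[ordered[:m]], y)
        kappa = cohen_kappa(y, tree.predict(X_train[ordered[:m]]))
        if kappa > best_kappa:    # strict: ties keep the smaller m
            best_tree, best_m, best_kappa = tree, m, kappa
    return PartitionModel(ordered_features=ordered, m=best_m, tree=best_tree,
                          train_kappa=float(best_kappa), seed=seed)


def predict_partition(model: PartitionModel, X_test: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.used_features if f not in X_test.columns]
    if missing:
        raise ValueError(f"test table lacks model features {missing}")
    return model.tree.predict(X_test[model.used_features])


# ---------------------------------------------------------------------------
# Prevalence-only benchmark


def fit_prevalence(y_train) -> PrevalenceModel:
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    probs = counts / counts.sum()
    return PrevalenceModel(class_probs=dict(zip(classes.tolist(), probs.tolist())))


def predict_prevalence(model: PrevalenceModel, n_test: int, seed) -> np.ndarray:
    """Independently assign each test patient a class at training prevalence."""
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = sorted(model.class_probs)
    p = np.array([model.class_probs[c] for c in classes])
    return rng.choice(np.array(classes, dtype=object), size=n_test, p=p)


# ---------------------------------------------------------------------------
# Combined-modality refit


def final_features(model) -> list[str]:
    """The feature set a fitted model actually uses."""
    if isinstance(model, APSModel):
        return list(model.subset)
    if isinstance(model, PartitionModel):
        return list(model.used_features)
    return []


def fit_combined(X_train: pd.DataFrame, y, ct_model, pet_model, method: str,
                 positive_class=None, seed: int | None = None, **kwargs):
    """Refit the chosen strategy on the union of the CT and PET final features.

    Only the model-fitting stage is re-run; screening is not repeated.
    """
    pool = sorted(set(final_features(ct_model)) | set(final_features(pet_model)))
    if not pool:
        raise FallbackToPrevalence("both modality models are empty")
    if method == APS:
        return fit_aps(X_train[pool], y, positive_class=positive_class, **kwargs)
    if method == PARTITION:
        return fit_partition(X_train[pool], y, seed=seed, **kwargs)
    raise ValueError(f"unknown method {method!r}")
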