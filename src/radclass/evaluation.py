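"""Cross-validation harness and validation statistics.

Replicated random 313/78-style splits (at the default cohort size), per-
replicate fitting of the requested model families on the training split only,
one-shot evaluation on the held-out split, and summaries as the median and
central-95% interval (2.5th/97.5th percentiles) across replicates.  Metrics
for multi-level outcomes are reported one-vs-rest per class.

The held-out rows live in a :class:`HoldoutVault` that raises if touched
before every model for the replicate is finalized, so train/test leakage is
structurally impossible rather than merely discouraged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from radclass.cohort import modality_of
from radclass.models import (
    APSModel,
    FallbackToPrevalence,
    PartitionModel,
    PrevalenceModel,
    final_features,
    fit_aps,
    fit_combined,
    fit_partition,
    fit_prevalence,
    predict_aps,
    predict_partition,
    predict_prevalence,
)
from radclass.preprocessing import (
    apply_transforms,
    cluster_features,
    fit_transforms,
    normalize_table,
    qc_filter,
)
from radclass.selection import (
    APS,
    PARTITION,
    PREVALENCE,
    select_aps_representatives,
    select_partition_representatives,
)

HISTOLOGY = "HISTOLOGY"
ORIGIN = "ORIGIN"
COMBINED = "COMBINED"

CT = "CT"
PET = "PET"
PETCT = "PETCT"

METRIC_COLUMNS = ("sensitivity", "specificity", "ppv", "npv", "youden",
                  "auc", "kappa")


# ---------------------------------------------------------------------------
# Validation statistics


def confusion_metrics(y_true, y_pred, positive_class) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and Youden for one positive class.

    Multi-level outcomes are reduced one-vs-rest by the caller passing each
    class in turn.  A metric whose denominator is empty (e.g. sensitivity
    with no true positives in the test set) is NaN and is dropped, not
    imputed, by the summaries.
    """
    t = np.asarray(y_true) == positive_class
    p = np.asarray(y_pred) == positive_class
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "youden": sens + spec - 1.0}


def auc(probabilities, y_true, positive_class) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    y01 = (np.asarray(y_true) == positive_class).astype(int)
    if y01.min() == y01.max():
        return math.nan
    return float(roc_auc_score(y01, np.asarray(probabilities, dtype=float)))


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    The degenerate case p_e = 1 (both sides constant and equal) is perfect
    agreement and is defined as 1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(np.unique(y_true)) == 1 and np.array_equal(y_true, y_pred):
        return 1.0
    return float(cohen_kappa_score(y_true, y_pred))


# ---------------------------------------------------------------------------
# Splits


@dataclass
class CVSplit:
    replicate: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int      # replicate seed; regenerates the split and all substreams


def _replicate_streams(seed: int):
    """(split, model, prevalence) seed sequences for one replicate."""
    return np.random.SeedSequence(seed).spawn(3)


def make_cv_splits(n_patients: int, n_replicates: int = 1000,
                   train_fraction: float = 313 / 391,
                   master_seed: int = 0,
                   stratify_labels=None) -> list[CVSplit]:
    """Simple random train/test splits, one per replicate.

    Train size is ``round(train_fraction * n)``; splits are unstratified by
    default (pass ``stratify_labels`` for a stratified sensitivity analysis).
    Replicate seeds derive from the master seed, so any replicate can be
    replayed in isolation from its logged seed.
    """
    if n_patients < 2:
        raise ValueError("need at least two patients to split")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_train = int(round(train_fraction * n_patients))
    if not 0 < n_train < n_patients:
        raise ValueError("train_fraction leaves an empty train or test set")
    rep_seeds = np.random.SeedSequence(master_seed).generate_state(
        n_replicates, dtype=np.uint64) % (2 ** 31)
    splits = []
    for rep, seed in enumerate(rep_seeds):
        seed = int(seed)
        split_ss, _, _ = _replicate_streams(seed)
        rng = np.random.default_rng(split_ss)
        if stratify_labels is None:
            perm = rng.permutation(n_patients)
            train = np.sort(perm[:n_train])
            test = np.sort(perm[n_train:])
        else:
            labels = np.asarray(stratify_labels)
            train_parts = []
            for level in np.unique(labels):
                idx = np.flatnonzero(labels == level)
                take = int(round(train_fraction * len(idx)))
                train_parts.append(rng.permutation(idx)[:take])
            train = np.sort(np.concatenate(train_parts))
            test = np.setdiff1d(np.arange(n_patients), train)
        splits.append(CVSplit(replicate=rep, train_idx=train, test_idx=test,
                              seed=seed))
    return splits


def regenerate_split(n_patients: int, n_train: int, replicate: int,
                     seed: int) -> CVSplit:
    """Rebuild one unstratified replicate's split from its logged seed."""
    split_ss, _, _ = _replicate_streams(seed)
    perm = np.random.default_rng(split_ss).permutation(n_patients)
    return CVSplit(replicate=replicate, train_idx=np.sort(perm[:n_train]),
                   test_idx=np.sort(perm[n_train:]), seed=seed)


# ---------------------------------------------------------------------------
# Leakage guard


class HoldoutVault:
    """Holds the held-out rows; access before :meth:`finalize` raises.

    Every pipeline replicate routes its test data through a vault, so a
    fitting stage that tried to peek at test values would crash the run.
    """

    def __init__(self, features: pd.DataFrame, y: np.ndarray):
        self._features = features
        self._y = np.asarray(y)
        self._finalized = False

    def finalize(self) -> None:
        self._finalized = True

    def _check(self) -> None:
        if not self._finalized:
            raise RuntimeError("test set accessed before model finalization")

    @property
    def features(self) -> pd.DataFrame:
        self._check()
        return self._features

    @property
    def y(self) -> np.ndarray:
        self._check()
        return self._y


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineOptions:
    """Thresholds and fitting options; defaults are the reference procedure's."""

    positive_class: str = "SCC"          # orientation of binary metrics/AUC
    k_clusters: int = 15
    missing_threshold: float = 0.20
    ratio_threshold: float = 1.5         # mean/median cut for skew transforms
    r2_threshold: float = 0.05
    p_threshold: float = 0.1
    min_expected_test: float = 5.0       # class reporting floor (combined task)
    impute_median: bool = False
    ridge: float = 1e-6
    rf_trees: int = 500
    rf_importance_repeats: int = 5
    tree_min_samples_leaf: int = 5


def task_labels(labels: pd.DataFrame, task: str) -> pd.Series:
    if task == HISTOLOGY:
        return labels["histology"]
    if task == ORIGIN:
        return labels["origin"]
    if task == COMBINED:
        return labels["origin"] + "_" + labels["histology"]
    raise ValueError(f"unknown task {task!r}")


def reported_classes(y: pd.Series, task: str, test_size: int,
                     options: PipelineOptions) -> list[str]:
    """Classes whose metrics are summarised.

    For the combined origin-and-histology task, classes too rare to appear
    reliably in a held-out set (expected test members below
    ``min_expected_test``) are trained on but not reported.
    """
    counts = y.value_counts()
    if task != COMBINED:
        return sorted(counts.index)
    frac = test_size / len(y)
    return sorted(c for c in counts.index
                  if counts[c] * frac >= options.min_expected_test)


def _prepare_modality(train_features: pd.DataFrame, modality: str,
                      options: PipelineOptions):
    """QC, transform and cluster one modality's training columns."""
    cols = [c for c in train_features.columns if modality_of(c) == modality]
    table, removal = qc_filter(train_features[cols],
                               missing_threshold=options.missing_threshold,
                               impute_median=options.impute_median)
    specs = fit_transforms(table, ratio_threshold=options.ratio_threshold)
    transformed = apply_transforms(table, specs)
    clusters = cluster_features(normalize_table(transformed), modality,
                                k=options.k_clusters)
    return transformed, specs, clusters, removal


def run_replicate(features: pd.DataFrame, y: pd.Series, split: CVSplit,
                  task: str, methods, modalities,
                  options: PipelineOptions,
                  classes: list[str] | None = None) -> tuple[list[dict], dict]:
    """Fit and evaluate one CV replicate.

    Returns (metric records, audit log).  The audit log carries the replicate
    seed, per-modality selections and fitted-model descriptions, which is
    enough to replay the replicate exactly.
    """
    methods = list(methods)
    modalities = list(modalities)
    y = np.asarray(y)
    if classes is None:
        classes = sorted(np.unique(y))
    multiclass = len(np.unique(y)) > 2
    if APS in methods and multiclass:
        raise ValueError(
            "APS supports binary outcomes only; use the partitioning method "
            "for three-level (or richer) outcomes")

    _, model_ss, prev_ss = _replicate_streams(split.seed)
    model_seeds = model_ss.generate_state(len(modalities) + 1) % (2 ** 31)
    seed_of = {mod: int(s) for mod, s in zip(modalities, model_seeds)}
    prev_rng = np.random.default_rng(prev_ss)

    X_train = features.iloc[split.train_idx]
    y_train = y[split.train_idx]
    vault = HoldoutVault(features.iloc[split.test_idx], y[split.test_idx])

    audit: dict = {"replicate": split.replicate, "seed": split.seed,
                   "selection": {}, "models": {}}
    fitted: dict[tuple[str, str], object] = {}
    specs_all: dict[str, object] = {}
    prevalence = fit_prevalence(y_train)

    single_mods = [m for m in (CT, PET) if m in modalities]
    prepared = {}
    if any(m in methods for m in (APS, PARTITION)):
        for mod in single_mods:
            prepared[mod] = _prepare_modality(X_train, mod, options)
            specs_all.update(prepared[mod][1])

    for method in (APS, PARTITION):
        if method not in methods:
            continue
        for mod in single_mods:
            transformed, _, clusters, _ = prepared[mod]
            if method == APS:
                selection = select_aps_representatives(
                    transformed, y_train, clusters,
                    r2_threshold=options.r2_threshold)
            else:
                selection = select_partition_representatives(
                    transformed, y_train, clusters,
                    p_threshold=options.p_threshold)
            audit["selection"][(method, mod)] = dict(selection.chosen)
            chosen = selection.features
            if not chosen:
                fitted[(method, mod)] = prevalence
                continue
            if method == APS:
                fitted[(method, mod)] = fit_aps(
                    transformed[chosen], y_train,
                    positive_class=options.positive_class, ridge=options.ridge)
            else:
                fitted[(method, mod)] = fit_partition(
                    transformed[chosen], y_train, seed=seed_of[mod],
                    n_trees=options.rf_trees,
                    min_samples_leaf=options.tree_min_samples_leaf,
                    importance_repeats=options.rf_importance_repeats)
        if PETCT in modalities:
            ct_model = fitted.get((method, CT))
            pet_model = fitted.get((method, PET))
            pool = sorted(set(final_features(ct_model))
                          | set(final_features(pet_model)))
            if not pool:
                fitted[(method, PETCT)] = prevalence
            else:
                train_all = pd.concat(
                    [prepared[m][0] for m in single_mods], axis=1)
                try:
                    fitted[(method, PETCT)] = fit_combined(
                        train_all, y_train, ct_model, pet_model, method,
                        positive_class=options.positive_class
                        if method == APS else None,
                        seed=seed_of[PETCT] if method == PARTITION else None,
                        **({"ridge": options.ridge} if method == APS else
                           {"n_trees": options.rf_trees,
                            "min_samples_leaf": options.tree_min_samples_leaf,
                            "importance_repeats":
                                options.rf_importance_repeats}))
                except FallbackToPrevalence:
                    fitted[(method, PETCT)] = prevalence
    if PREVALENCE in methods:
        fitted[(PREVALENCE, "PREV")] = prevalence

    for (method, mod), model in fitted.items():
        audit["models"][(method, mod)] = model.describe()

    # --- everything below is evaluation: the vault opens here -------------
    vault.finalize()
    X_test, y_test = vault.features, vault.y

    records: list[dict] = []
    for (method, mod) in sorted(fitted):
        model = fitted[(method, mod)]
        probs = None
        if isinstance(model, PrevalenceModel):
            y_pred = predict_prevalence(model, len(y_test), prev_rng)
        else:
            needed = final_features(model)
            test_t = apply_transforms(
                X_test[needed], {f: specs_all[f] for f in needed})
            if isinstance(model, APSModel):
                y_pred, probs = predict_aps(model, test_t)
            else:
                y_pred = predict_partition(model, test_t)
        kappa = cohen_kappa(y_test, y_pred)
        for cls in classes:
            row = {"replicate": split.replicate, "method": method,
                   "modality": mod, "cls": cls,
                   "fallback": method != PREVALENCE
                   and isinstance(model, PrevalenceModel)}
            row.update(confusion_metrics(y_test, y_pred, positive_class=cls))
            row["auc"] = (auc(probs, y_test, cls)
                          if probs is not None and cls == options.positive_class
                          else math.nan)
            row["kappa"] = kappa
            records.append(row)
    return records, audit


def run_pipeline(features: pd.DataFrame, labels: pd.DataFrame, task: str,
                 methods, modalities, splits: list[CVSplit],
                 options: PipelineOptions | None = None,
                 collect_audit: bool = False):
    """Run the full CV harness; returns a tidy DataFrame of MetricsRecords.

    One row per (replicate, method, modality, class); prevalence rows carry
    modality ``"PREV"``.  With ``collect_audit=True`` returns
    ``(records, audits)``.
    """
    options = options or PipelineOptions()
    y = task_labels(labels, task)
    if task != HISTOLOGY and APS in methods:
        raise ValueError(
            "APS supports binary outcomes only; use the partitioning method "
            "for three-level (or richer) outcomes")
    classes = reported_classes(y, task, len(splits[0].test_idx), options)
    records: list[dict] = []
    audits: list[dict] = []
    for split in splits:
        rec, audit = run_replicate(features, y, split, task, methods,
                                   modalities, options, classes=classes)
        records.extend(rec)
        audits.append(audit)
    frame = pd.DataFrame.from_records(records)
    return (frame, audits) if collect_audit else frame


# ---------------------------------------------------------------------------
# Summaries


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Median and central-95% interval per (method, modality, class, metric).

    Percentiles use linear interpolation between order statistics; NaN cells
    (undefined metrics in rare-class replicates) are dropped and counted.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    long = records.melt(id_vars=["method", "modality", "cls"],
                        value_vars=[c for c in METRIC_COLUMNS
                                    if c in records.columns],
                        var_name="metric", value_name="value")
    rows = []
    for key, grp in long.groupby(["method", "modality", "cls", "metric"],
                                 sort=True):
        vals = grp["value"].dropna().to_numpy()
        n_missing = int(grp["value"].isna().sum())
        if len(vals) == 0:
            med = low = high = math.nan
        else:
            med = float(np.percentile(vals, 50))
            low = float(np.percentile(vals, 2.5))
            high = float(np.percentile(vals, 97.5))
        rows.append(dict(zip(("method", "modality", "cls", "metric"), key),
                         median=med, low=low, high=high,
                         n_used=len(vals), n_missing=n_missing))
    out = pd.DataFrame(rows)
    return out[~(out["metric"] == "auc") | (out["n_used"] > 0)].reset_index(drop=True)


def format_summary(summary: pd.DataFrame) -> str:
    """Render a summary as per-class blocks, one column per method/modality."""
    lines = []
    summary = summary.copy()
    summary["column"] = np.where(summary["method"] == PREVALENCE, "Prevalence",
                                 summary["method"] + "/" + summary["modality"])
    for cls, block in summary.groupby("cls"):
        lines.append(f"== class {cls} ==")
        pivot = block.pivot_table(index="metric", columns="column",
                                  values=["median", "low", "high"])
        for metric in block["metric"].unique():
            cells = []
            for col in sorted(block["column"].unique()):
                try:
                    med = pivot.loc[metric, ("median", col)]
                    lo = pivot.loc[metric, ("low", col)]
                    hi = pivot.loc[metric, ("high", col)]
                except KeyError:
                    continue
                if not math.isnan(med):
                    cells.append(f"{col}: {med:.2f} ({lo:.2f}, {hi:.2f})")
            if cells:
                lines.append(f"  {metric:<12} " + "   ".join(cells))
    return "\n".join(lines)
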