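"""Synthetic radiomics cohort generator.

Emulates the statistical structure of a PET/CT radiomics feature table at the
cohort composition of the 391-patient study population (three anatomical
origins crossed with two histologies): blocks of correlated features driven
by per-cluster latent factors, class-dependent latent mean shifts,
right-skewed features (mean/median > 1.5), features with missing values, and
zero-variance columns.  Feature values are simulated numbers whose names only
mimic radiomics feature families; no image quantities are computed.

Model: for modality ``m`` and cluster ``c``, each patient ``i`` draws a latent
factor ``z_i ~ Normal(delta_c(class_i), 1)``; each of the cluster's features
is ``loading * z_i + sqrt(1 - loading^2) * eps_ij`` with independent standard
normal noise, so the expected within-cluster feature correlation is
``loading^2`` and between-cluster correlation is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ORIGINS = ("GE", "HN", "PULM")
HISTOLOGIES = ("AC", "SCC")
MODALITIES = ("CT", "PET")

# feature-name families; naming only, nothing is computed from images
_FAMILIES = ("Conventional", "Discretized", "Shape", "GLCM", "GLRLM", "NGLDM", "GLZLM")

# additive shift applied to skewed columns that must contain zeros/negatives;
# exp(N(0,1)) - 0.5 keeps mean/median ratio > 1.5 while the minimum goes < 0
_SIGNED_SKEW_SHIFT = 0.5


def class_key(origin: str, histology: str) -> str:
    return f"{origin}_{histology}"


CLASS_KEYS = tuple(class_key(o, h) for o in ORIGINS for h in HISTOLOGIES)


def histology_effect(delta: float, positive: str = "SCC") -> dict[str, float]:
    """Latent mean shift carried by histology: ``positive`` class shifted by delta."""
    return {class_key(o, h): (delta if h == positive else 0.0)
            for o in ORIGINS for h in HISTOLOGIES}


def origin_effect(shifts: dict[str, float]) -> dict[str, float]:
    """Latent mean shift carried by anatomical origin."""
    return {class_key(o, h): shifts.get(o, 0.0)
            for o in ORIGINS for h in HISTOLOGIES}


def cluster_id(modality: str, index: int) -> str:
    return f"{modality}_c{index:02d}"


def cluster_feature_names(modality: str, n_clusters: int,
                          features_per_cluster: int) -> dict[str, list[str]]:
    """Deterministic modality-tagged feature names, keyed by cluster id."""
    names: dict[str, list[str]] = {}
    for ci in range(n_clusters):
        family = _FAMILIES[ci % len(_FAMILIES)]
        names[cluster_id(modality, ci)] = [
            f"{modality}_{family}_c{ci:02d}f{j:02d}"
            for j in range(features_per_cluster)
        ]
    return names


class ConfigError(ValueError):
    """Raised for an internally inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``class_counts`` maps ``(origin, histology)`` to a patient count and must
    sum to ``n_patients``.  ``effect_sizes`` maps a cluster id (e.g.
    ``"CT_c00"``) to a per-class latent mean shift in latent-factor SD units.
    ``missing_features`` lists ``(feature name, MCAR missingness rate)`` pairs.
    """

    n_patients: int
    class_counts: dict[tuple[str, str], int]
    n_clusters_per_modality: int = 15
    features_per_cluster: int = 10
    within_cluster_loading: float = 0.8
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    skewed_fraction: float = 0.2
    signed_skew_fraction: float = 0.25
    missing_features: tuple[tuple[str, float], ...] = ()
    n_constant_features: int = 2
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_counts.values())
        if total != self.n_patients:
            raise ConfigError(
                f"class_counts sum to {total}, expected n_patients={self.n_patients}")
        if not 0.0 <= self.within_cluster_loading <= 1.0:
            raise ConfigError("within_cluster_loading must be in [0, 1]")
        for name, rate in self.missing_features:
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"missingness rate for {name} must be in [0, 1)")
        for frac_name in ("skewed_fraction", "signed_skew_fraction"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{frac_name} must be in [0, 1]")

    def feature_names(self) -> list[str]:
        """All feature column names in generation order (constants last per modality)."""
        out: list[str] = []
        for mod in MODALITIES:
            by_cluster = cluster_feature_names(
                mod, self.n_clusters_per_modality, self.features_per_cluster)
            for names in by_cluster.values():
                out.extend(names)
        out.extend(self._constant_names())
        return out

    def _constant_names(self) -> list[str]:
        return [f"{MODALITIES[j % 2]}_QC_const{j:02d}"
                for j in range(self.n_constant_features)]


@dataclass
class GroundTruth:
    """What the generator planted: used as the oracle in recovery checks."""

    cluster_of: dict[str, str]                 # feature -> cluster id
    signal_clusters: dict[str, dict[str, float]]  # cluster id -> nonzero class shifts
    skewed_features: list[str]
    signed_skew_features: list[str]
    constant_features: list[str]
    missing_features: dict[str, float]


@dataclass
class SyntheticCohort:
    features: pd.DataFrame   # patients x features, NaN where missing
    labels: pd.DataFrame     # columns: origin, histology (index = patient_id)
    ground_truth: GroundTruth


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the latent-factor model.

    Regenerating with an identical config (including seed) yields bit-identical
    tables; labels follow ``class_counts`` exactly.  One shared seed drives a
    per-purpose seed sequence (labels, factors, noise, skew placement,
    missingness, constants) so each component is independently reproducible.
    """
    config.validate()
    n = config.n_patients
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_labels, rng_factors, rng_noise, rng_skew, rng_missing, rng_const = (
        np.random.default_rng(s) for s in streams)

    # labels: exact class counts, order randomised
    pairs: list[tuple[str, str]] = []
    for (origin, hist) in sorted(config.class_counts):
        pairs.extend([(origin, hist)] * config.class_counts[(origin, hist)])
    order = rng_labels.permutation(n)
    pairs = [pairs[i] for i in order]
    patient_ids = [f"P{i:04d}" for i in range(n)]
    labels = pd.DataFrame(
        {"origin": [p[0] for p in pairs], "histology": [p[1] for p in pairs]},
        index=pd.Index(patient_ids, name="patient_id"))
    keys = np.array([class_key(o, h) for o, h in pairs])

    lam = config.within_cluster_loading
    noise_scale = np.sqrt(1.0 - lam ** 2)
    columns: dict[str, np.ndarray] = {}
    cluster_of: dict[str, str] = {}
    for mod in MODALITIES:
        by_cluster = cluster_feature_names(
            mod, config.n_clusters_per_modality, config.features_per_cluster)
        for cid, names in by_cluster.items():
            shifts = config.effect_sizes.get(cid, {})
            delta = np.array([shifts.get(k, 0.0) for k in keys])
            z = delta + rng_factors.standard_normal(n)
            for name in names:
                eps = rng_noise.standard_normal(n)
                columns[name] = lam * z + noise_scale * eps
                cluster_of[name] = cid

    # right-skew a fraction of the cluster features; a sub-fraction is shifted
    # so it contains zeros/negatives and exercises the signed-sqrt transform
    cluster_cols = list(columns)
    n_skew = int(round(config.skewed_fraction * len(cluster_cols)))
    skewed = sorted(rng_skew.choice(cluster_cols, size=n_skew, replace=False))
    n_signed = int(round(config.signed_skew_fraction * n_skew))
    signed = skewed[:n_signed]
    for name in skewed:
        columns[name] = np.exp(columns[name])
        if name in signed:
            columns[name] = columns[name] - _SIGNED_SKEW_SHIFT

    constant_names = config._constant_names()
    for name in constant_names:
        columns[name] = np.full(n, np.round(rng_const.normal(loc=1.0), 2))

    features = pd.DataFrame(columns, index=labels.index)

    for name, rate in config.missing_features:
        if name not in features.columns:
            raise ConfigError(f"missing_features names unknown feature {name!r}")
        mask = rng_missing.random(n) < rate
        features.loc[mask, name] = np.nan

    signal = {cid: {k: v for k, v in shifts.items() if v != 0.0}
              for cid, shifts in config.effect_sizes.items()
              if any(v != 0.0 for v in shifts.values())}
    truth = GroundTruth(
        cluster_of=cluster_of,
        signal_clusters=signal,
        skewed_features=list(skewed),
        signed_skew_features=list(signed),
        constant_features=constant_names,
        missing_features=dict(config.missing_features),
    )
    return SyntheticCohort(features=features, labels=labels, ground_truth=truth)


def reference_cohort_config(seed: int = 0) -> CohortConfig:
    """Config preloaded with the study cohort's printed composition.

    391 patients: gastroesophageal 128 (76 AC / 52 SCC), head & neck 121
    (2 AC / 119 SCC), pulmonary 142 (94 AC / 48 SCC); hence 172 AC and
    219 SCC overall.  Signal placement, skew, missingness and constant
    columns are package defaults chosen to exercise every pipeline branch;
    the source data's feature distributions are not characterised anywhere,
    so these are free parameters.
    """
    class_counts = {
        ("GE", "AC"): 76, ("GE", "SCC"): 52,
        ("HN", "AC"): 2, ("HN", "SCC"): 119,
        ("PULM", "AC"): 94, ("PULM", "SCC"): 48,
    }
    effect_sizes = {
        "CT_c00": histology_effect(0.8),
        "CT_c01": histology_effect(0.6),
        "CT_c02": origin_effect({"PULM": 1.0}),
        "CT_c03": origin_effect({"GE": 0.8, "HN": -0.4}),
        "PET_c00": histology_effect(0.4),
        "PET_c01": origin_effect({"HN": 0.5}),
    }
    config = CohortConfig(
        n_patients=391,
        class_counts=class_counts,
        effect_sizes=effect_sizes,
        seed=seed,
    )
    names = config.feature_names()
    # all rates above the 20% QC cut-off: once these columns are removed no
    # missing data remain, matching the study cohort's post-QC completeness
    config.missing_features = (
        (names[50], 0.25), (names[61], 0.30), (names[72], 0.22), (names[83], 0.40))
    return config


# ---------------------------------------------------------------------------
# CSV / JSON I/O


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> tuple[Path, Path]:
    """Write ``cohort.csv`` (labels + features, empty cells for missing) and a
    ``ground_truth.json`` sidecar; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = pd.concat([cohort.labels, cohort.features], axis=1)
    csv_path = directory / "cohort.csv"
    table.to_csv(csv_path, na_rep="")
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(json.dumps(asdict(cohort.ground_truth), indent=1))
    return csv_path, truth_path


def read_cohort(csv_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV; returns ``(features, labels)``.

    Expects a ``patient_id`` first column, label columns ``origin`` and
    ``histology``, and modality-tagged feature columns (``CT_*`` / ``PET_*``).
    """
    table = pd.read_csv(csv_path, index_col="patient_id")
    label_cols = [c for c in ("origin", "histology") if c in table.columns]
    if len(label_cols) < 2:
        raise ValueError(
            "cohort CSV must contain 'origin' and 'histology' label columns")
    features = table.drop(columns=label_cols)
    bad = [c for c in features.columns if modality_of(c) is None]
    if bad:
        raise ValueError(f"feature columns without a CT_/PET_ modality tag: {bad[:5]}")
    return features, table[label_cols]


def modality_of(feature_name: str) -> str | None:
    """Modality tag encoded in a feature name, or None if untagged."""
    for mod in MODALITIES:
        if feature_name.startswith(mod + "_"):
            return mod
    return None
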