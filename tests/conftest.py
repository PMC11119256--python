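import numpy as np
import pandas as pd
import pytest

from radclass.cohort import (
    CohortConfig,
    generate_cohort,
    histology_effect,
    reference_cohort_config,
)


def balanced_config(n_per_class: int = 10, **overrides) -> CohortConfig:
    """Small cohort with equal counts in all six origin x histology classes."""
    counts = {(o, h): n_per_class
              for o in ("GE", "HN", "PULM") for h in ("AC", "SCC")}
    defaults = dict(
        n_patients=6 * n_per_class,
        class_counts=counts,
        n_clusters_per_modality=4,
        features_per_cluster=3,
        skewed_fraction=0.0,
        n_constant_features=0,
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def reference_cohort():
    """The default 391-patient synthetic cohort."""
    return generate_cohort(reference_cohort_config(seed=7))


@pytest.fixture(scope="session")
def signal_cohort():
    """391 patients, three strong histology-signal CT clusters (delta 1.5,
    loading 0.8) amid null clusters; the conditions for recovery checks."""
    config = reference_cohort_config(seed=11)
    config.effect_sizes = {f"CT_c{i:02d}": histology_effect(1.5) for i in range(3)}
    config.missing_features = ()
    return generate_cohort(config)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)


def feature_frame(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Feature table keyed by plain arrays, CT-tagged unless already tagged."""
    cols = {}
    for name, x in values.items():
        tagged = name if name.startswith(("CT_", "PET_")) else f"CT_{name}"
        cols[tagged] = np.asarray(x, dtype=float)
    return pd.DataFrame(cols)
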