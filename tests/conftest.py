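import numpy as np
import pandas as pd
import pytest

from swimmetab.dataset import AbundanceDataset, META_COLUMNS
from swimmetab.synthio import CohortConfig, generate_cohort


SMALL_FEATURES = {"ffa": 5, "glycolytic": 3, "lipoprotein": 4, "inert": 8}


@pytest.fixture
def small_config() -> CohortConfig:
    """A compact cohort: 16 participants, 20 features, no missingness."""
    return CohortConfig(
        n_features_per_class=dict(SMALL_FEATURES),
        missing_rate=0.0,
        n_qc=5,
        seed=42,
    )


@pytest.fixture
def noise_free_config() -> CohortConfig:
    """All variance sources zeroed: post/pre ratios are exactly the planted
    effects."""
    return CohortConfig(
        n_features_per_class=dict(SMALL_FEATURES),
        effect_matrix={},
        sex_modulation=0.0,
        sd_participant=0.0,
        sd_residual_by_trial={"moderate": 0.0, "heavy": 0.0, "severe": 0.0},
        baseline_log_sd=0.0,
        missing_rate=0.0,
        n_qc=0,
        seed=1,
    )


@pytest.fixture
def small_dataset(small_config) -> AbundanceDataset:
    return generate_cohort(small_config).dataset


def make_dataset(values, sample_types=None, platforms=None, trials=None,
                 timepoints=None, participants=None) -> AbundanceDataset:
    """Hand-build a small AbundanceDataset for fixture-style tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_types = sample_types or ["study"] * n
    sample_ids = [f"S{i:02d}" for i in range(n)]
    n_study = sum(1 for s in sample_types if s == "study")
    default_participants = iter([f"P{i:02d}" for i in range(n)])
    meta = []
    k = 0
    for i, stype in enumerate(sample_types):
        if stype == "study":
            meta.append(
                {
                    "participant_id": participants[k] if participants else next(default_participants),
                    "sex": "female",
                    "trial": trials[k] if trials else "moderate",
                    "timepoint": timepoints[k] if timepoints else "pre",
                    "sample_type": "study",
                    "injection_order": i + 1,
                }
            )
            k += 1
        else:
            meta.append(
                {
                    "participant_id": "",
                    "sex": "",
                    "trial": "",
                    "timepoint": "",
                    "sample_type": "qc",
                    "injection_order": i + 1,
                }
            )
    meta = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))[META_COLUMNS]
    feature_ids = pd.Index([f"F{j:02d}" for j in range(p)], name="feature_id")
    matrix = pd.DataFrame(values, index=meta.index, columns=feature_ids)
    feats = pd.DataFrame(
        {"platform": platforms if platforms else ["lcms-lipid"] * p}, index=feature_ids
    )
    return AbundanceDataset(matrix, meta, feats)
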