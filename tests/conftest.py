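import numpy as np
import pandas as pd
import pytest

from sedeeg.features import FEATURE_NAMES
from sedeeg.preprocess import preprocess_recording
from sedeeg.features import extract_features
from sedeeg.synth import GeneratorConfig, generate_cohort


def make_feature_df(n_recordings=6, epochs_per=40, n_informative=3, effect=2.0,
                    seed=0, age_groups=None):
    """Synthetic feature matrix (no EEG): 44 columns in canonical order,
    the first ``n_informative`` shifted by ``effect`` SD between classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_recordings):
        age = (
            rng.uniform(*age_groups[r % len(age_groups)])
            if age_groups
            else rng.uniform(18, 70)
        )
        sex = "male" if r % 2 == 0 else "female"
        for e in range(epochs_per):
            label = "sedated" if e % 2 == 0 else "awake"
            x = rng.standard_normal(44)
            if label == "sedated":
                x[:n_informative] += effect
            rows.append(
                {
                    "recording_id": f"rec{r:02d}",
                    "subject_id": f"sub{r:02d}",
                    "segment_index": e // 15,
                    "epoch_index": e % 15,
                    "label": label,
                    "age_years": age,
                    "sex": sex,
                    "drug": "propofol",
                    "remifentanil": False,
                    **dict(zip(FEATURE_NAMES, x)),
                }
            )
    return pd.DataFrame(rows)


def cohort_features(config: GeneratorConfig) -> pd.DataFrame:
    """Generate -> preprocess -> extract features for a whole cohort."""
    kept = []
    for rec in generate_cohort(config):
        k, _ = preprocess_recording(rec)
        kept.extend(k)
    return extract_features(kept)


@pytest.fixture(scope="session")
def high_contrast_features():
    """Feature matrix of a 6-recording cohort with the default (strong)
    awake/sedated spectral contrast; reused by several evaluation tests."""
    return cohort_features(GeneratorConfig(n_subjects=6, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
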