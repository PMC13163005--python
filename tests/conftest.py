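import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import diagxai as d

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-patient class-conditional cohort at the study prevalence."""
    spec = d.default_cohort_spec(n=400, seed=42, prevalence=0.85)
    return d.generate_cohort(spec)


@pytest.fixture(scope="session")
def fast_config() -> d.ModelConfig:
    """Lighter ensemble for unit tests where the study size is not the point."""
    return d.ModelConfig(n_trees=50, seed=3)


@pytest.fixture(scope="session")
def small_oof(small_cohort, fast_config):
    y = small_cohort["outcome"].to_numpy(dtype=int)
    folds = d.stratified_folds(y, k=5, seed=1)
    features = [c for c in small_cohort.columns if c not in ("patient_id", "outcome")]
    preds = d.oof_predict(small_cohort, features, fast_config, folds)
    return small_cohort, folds, preds


def naive_interventional_phi(predict_fn, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Independent brute-force marginalization oracle.

    Loops patient by patient, feature by feature, background row by background
    row, evaluating the model on one modified row at a time.
    """
    n, k = X.shape
    m = background.shape[0]
    phi = np.zeros((n, k))
    for i in range(n):
        p_i = float(predict_fn(X[i:i + 1])[0])
        for j in range(k):
            acc = 0.0
            for r in range(m):
                row = X[i].copy()
                row[j] = background[r, j]
                acc += float(predict_fn(row[None, :])[0])
            phi[i, j] = p_i - acc / m
    return phi
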