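import numpy as np
import pandas as pd
import pytest

from facerisk import synth_data as sd


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject image cohort shared across extraction tests."""
    cfg = sd.SyntheticConfig(n_per_class=3, image_size=64, seed=42)
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_table():
    """Feature table with no class effect and independent features."""
    cfg = sd.SyntheticConfig(n_per_class=100, seed=7, corr_structure=None)
    return sd.generate_feature_table(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_model_table():
    """Separable-ish 6-feature table for model/attribution tests."""
    r = np.random.default_rng(3)
    n = 200
    X = r.normal(size=(n, 6))
    logits = 1.5 * X[:, 0] - 1.0 * X[:, 1]
    y = (r.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    table = pd.DataFrame(X, columns=[f"f{j}" for j in range(6)])
    table["label"] = y
    return table
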