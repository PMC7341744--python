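import numpy as np
import pandas as pd
import pytest

from samgap import ModelSpec, default_config, generate_lms_fixture, generate_population

DEFAULT_COVARIATES = {
    "wealth": "categorical",
    "maternal_education": "categorical",
    "improved_water": "categorical",
    "media_access": "categorical",
    "child_age": "continuous",
}


@pytest.fixture(scope="session")
def lms():
    return generate_lms_fixture(seed=1)


@pytest.fixture(scope="session")
def model_spec():
    return ModelSpec(outcome="sam", covariates=DEFAULT_COVARIATES)


@pytest.fixture(scope="session")
def small_world():
    """A modest clustered two-group dataset with real rural-urban gaps."""
    cfg = default_config(n_neighbourhoods=400, mean_children_per_neighbourhood=15, seed=5)
    return generate_population(cfg).records


@pytest.fixture()
def toy_children():
    """Six children, two clusters, hand-checkable numbers."""
    return pd.DataFrame(
        {
            "country": "T",
            "cluster_id": ["a", "a", "a", "b", "b", "b"],
            "weight": [1.0, 1.0, 2.0, 1.0, 3.0, 1.0],
            "residence": ["rural", "rural", "rural", "urban", "urban", "urban"],
            "x": [0.0, 1.0, 1.0, 0.0, 0.0, 1.0],
            "sam": [1, 0, 0, 0, 1, 0],
        }
    )


def weighted_mean(v, w):
    v, w = np.asarray(v, float), np.asarray(w, float)
    return (v * w).sum() / w.sum()
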