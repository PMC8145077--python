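import warnings

import pytest
from hypothesis import HealthCheck, settings

import demrisk as d

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort2528():
    """One cohort at the study's consensus-sample size, fixed seed."""
    return d.generate_cohort(d.CohortSpec(n_total=2528, seed=7))


@pytest.fixture(scope="session")
def labeled2528(cohort2528):
    return d.label_dementia(cohort2528)


@pytest.fixture(scope="session")
def train_test(labeled2528):
    split = d.split_70_30(labeled2528, seed=3)
    train = labeled2528[labeled2528["id"].isin(split.train_ids)]
    test = labeled2528[labeled2528["id"].isin(split.test_ids)]
    return train, test


FAST_GRIDS = {
    "gradient_boosting": {"n_estimators": [150], "max_depth": [2]},
    "random_forest": {"n_estimators": [300]},
    "svm_rbf": {"clf__C": [1.0, 10.0]},
    "elastic_net": {"clf__C": [1.0], "clf__l1_ratio": [0.5]},
    "regression_splines": {"spline__n_knots": [5], "clf__C": [1.0]},
    "mlp": {"clf__hidden_layer_sizes": [(5,)], "clf__alpha": [1e-3]},
}


@pytest.fixture(scope="session")
def fast_grids():
    """Single-point (or two-point) grids for quick end-to-end fits."""
    return FAST_GRIDS
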