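import numpy as np
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from evostack.features import FeatureSpec, TrialSignal, build_design_set
from evostack.learners import BaseLearnerSpec
from evostack.synth import MultisineSpec, make_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cheap_specs():
    """Five fast learners for structural stacking tests (the stack only
    requires five estimator factories, not the production set)."""
    return [
        BaseLearnerSpec("ols", lambda p, s: LinearRegression(), {"_": [0]}),
        BaseLearnerSpec("ridge", lambda p, s: Ridge(alpha=p["alpha"]),
                        {"alpha": [1e-6, 1.0]}),
        BaseLearnerSpec("lasso", lambda p, s: Lasso(alpha=0.001, max_iter=5000),
                        {"_": [0]}),
        BaseLearnerSpec("tree", lambda p, s: DecisionTreeRegressor(
            max_depth=4, random_state=0), {"_": [0]}),
        BaseLearnerSpec("knn", lambda p, s: KNeighborsRegressor(
            n_neighbors=p["k"]), {"k": [5]}),
    ]


def dummy_specs():
    """Five mean predictors (for contract tests that ignore accuracy)."""
    return [
        BaseLearnerSpec(f"dummy{i}", lambda p, s: DummyRegressor(), {"_": [0]})
        for i in range(5)
    ]


@pytest.fixture(scope="session")
def tiny_participant():
    """One noisy synthetic participant, half-second signals."""
    return make_benchmark(1, MultisineSpec(seconds=0.5), seed=99)[0]


@pytest.fixture(scope="session")
def tiny_design(tiny_participant):
    return build_design_set(tiny_participant.train, FeatureSpec())


def make_trial(u, y, participant=1, signal_id=1):
    return TrialSignal(participant, signal_id, np.asarray(u, float),
                       np.asarray(y, float))
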