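import numpy as np
import pytest

import enoseopt as eo
from enoseopt.features import pivot_features
from enoseopt.select import SelectorConfig, SubsetEvaluator


@pytest.fixture(scope="session")
def small_dataset():
    """Two-temperature, three-class dataset used by several test modules."""
    scenarios = eo.default_scenarios(temperatures=(4.0, 20.0))
    return eo.generate_dataset(scenarios, n_cycles_per_class=8, seed=42)


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    return eo.preprocess_dataset(small_dataset)


@pytest.fixture(scope="session")
def feature_tab(preprocessed):
    return eo.feature_table(preprocessed.cycles)


@pytest.fixture(scope="session")
def evaluator(feature_tab):
    X, y, temps = pivot_features(feature_tab)
    return SubsetEvaluator(X, y, temps, SelectorConfig(), seed=42)


@pytest.fixture(scope="session")
def default_dataset():
    """Full four-temperature dataset at the bundled default scale."""
    scenarios = eo.default_scenarios()
    return eo.generate_dataset(scenarios, n_cycles_per_class=12, seed=1)


@pytest.fixture(scope="session")
def default_evaluator(default_dataset):
    res = eo.preprocess_dataset(default_dataset)
    tab = eo.feature_table(res.cycles)
    X, y, temps = pivot_features(tab)
    return SubsetEvaluator(X, y, temps, SelectorConfig(), seed=1)
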