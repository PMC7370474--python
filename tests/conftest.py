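import numpy as np
import pandas as pd
import pytest

from pheoihd.cohort import Cohort, FeatureSpec


def make_cohort(columns: dict, labels, specs=None) -> Cohort:
    """Assemble a Cohort from raw columns, inferring simple specs if needed."""
    frame = pd.DataFrame(columns)
    labels = np.asarray(labels, dtype=int)
    if specs is None:
        specs = []
        for name in frame.columns:
            values = set(frame[name].unique())
            if values <= {0, 1}:
                specs.append(FeatureSpec(name, "bernoulli",
                                         {0: {"p": 0.5}, 1: {"p": 0.5}}))
            else:
                specs.append(FeatureSpec(name, "normal",
                                         {0: {"mean": 0.0, "sd": 1.0},
                                          1: {"mean": 0.0, "sd": 1.0}}))
    return Cohort(frame, labels, tuple(specs))


@pytest.fixture
def toy_cohort() -> Cohort:
    """Four patients, two classes: feature `a` equals the label, `b` constant."""
    return make_cohort({"a": [0, 0, 1, 1], "b": [7.0, 7.0, 7.0, 7.0]},
                       [0, 0, 1, 1])


@pytest.fixture
def signal_cohort() -> Cohort:
    """Imbalanced cohort (1:2.82-style) with one strongly separated feature."""
    rng = np.random.default_rng(42)
    n0, n1 = 209, 74
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
    signal = np.r_[rng.normal(0, 1, n0), rng.normal(2, 1, n1)]
    noise = rng.normal(0, 1, n0 + n1)
    return make_cohort({"signal": signal, "noise": noise}, labels)
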