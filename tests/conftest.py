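import numpy as np
import pytest

import harspec as h
from harspec.features import FeatureSet


@pytest.fixture(scope="session")
def default_specs():
    return h.default_specs()


@pytest.fixture(scope="session")
def small_streams(default_specs):
    """Three streams per class, 10 s at 50 Hz — enough for 5 windows each."""
    return h.make_dataset(list(default_specs.values()), 3, 50.0, seed=11,
                          duration_s=10.0)


@pytest.fixture(scope="session")
def or_features(small_streams):
    return h.build_feature_set(small_streams)


def make_feature_set(class_counts: dict[str, int], n_features: int = 4,
                     seed: int = 0) -> FeatureSet:
    """Random non-negative feature set with given per-class row counts."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, n in class_counts.items():
        rows.append(rng.uniform(0, 10, size=(n, n_features)))
        labels.extend([cls] * n)
    return FeatureSet(X=np.vstack(rows), labels=np.asarray(labels))
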