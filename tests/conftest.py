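import numpy as np
import pytest

from metaboselect.dataio import FeatureTable
from metaboselect.synthdata import SynthSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(x: np.ndarray, labels=None, feature_ids=None) -> FeatureTable:
    """Wrap a raw matrix in a FeatureTable with default ids/labels."""
    n, p = x.shape
    if labels is None:
        labels = np.where(np.arange(n) < n // 2, 1, -1)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=feature_ids,
        intensities=x,
        labels=np.asarray(labels),
    )


@pytest.fixture
def small_informative_table():
    """50-sample, 30-feature table with 3 planted features and one cluster."""
    spec = SynthSpec(
        n_case=25,
        n_control=25,
        n_features=30,
        n_informative=3,
        effect_size=1.5,
        cluster_sizes=[3, 3],
        within_cluster_r=0.8,
        seed=7,
    )
    return generate_dataset(spec), spec
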