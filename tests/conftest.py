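import numpy as np
import pytest

from gasselect.data_model import Dataset
from gasselect.synthetic_data import GeneratorSpec, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_dataset():
    """40 rows, 4 classes, 3 features; labels depend on the first feature."""
    rng = np.random.default_rng(7)
    n = 40
    x0 = np.repeat([0.0, 1.0, 2.0, 3.0], 10) + 0.05 * rng.standard_normal(n)
    features = np.column_stack([x0, rng.standard_normal(n), rng.standard_normal(n)])
    labels = np.repeat(["a", "b", "c", "d"], 10).astype(object)
    perm = rng.permutation(n)
    return Dataset(features[perm], labels[perm], ["f1", "f2", "f3"], ["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-signal dataset: 3 informative + 9 noise, strong effect."""
    spec = GeneratorSpec(
        class_counts=(60, 60, 60, 60),
        n_informative=3,
        n_noise=9,
        effect_size=3.0,
        seed=11,
    )
    return generate_dataset(spec)
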