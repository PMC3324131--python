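import numpy as np
import pytest

from genosl.genotype import Dataset, GenotypeMatrix


def make_dataset(X, y, labels=None, ids=None) -> Dataset:
    X = np.asarray(X)
    n, p = X.shape
    return Dataset(
        genotype=GenotypeMatrix(
            values=X,
            patient_ids=ids or [f"P{i}" for i in range(n)],
            mutation_labels=labels or [f"v{j + 1}" for j in range(p)],
        ),
        outcome=np.asarray(y, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng) -> Dataset:
    """n=30, p=4 binary dataset with a simple linear signal."""
    X = (rng.random((30, 4)) < 0.5).astype(int)
    y = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 2] + rng.normal(0, 0.3, 30)
    return make_dataset(X, y)


@pytest.fixture
def cohort():
    from genosl.synthetic_data import default_config, generate_cohort

    return generate_cohort(default_config(seed=0))
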