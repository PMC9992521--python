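import numpy as np
import pytest

from vewselect import ExpressionDataset, SyntheticSpec, generate_dataset, preprocess


def make_dataset(values, labels=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if labels is None:
        labels = ["a"] * (m // 2) + ["b"] * (m - m // 2)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n)]
    return ExpressionDataset(values, gene_ids, np.asarray(labels, dtype=object))


@pytest.fixture
def separable_dataset():
    """Gene 0 perfectly separates two classes; genes 1-9 are pure noise.

    Values already lie in [0, 1] so no preprocessing is needed.
    """
    rng = np.random.default_rng(7)
    m = 40
    values = rng.uniform(0.0, 1.0, size=(m, 10))
    labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
    values[:20, 0] = rng.uniform(0.0, 0.2, size=20)
    values[20:, 0] = rng.uniform(0.8, 1.0, size=20)
    return ExpressionDataset(values, [f"g{j}" for j in range(10)], labels)


@pytest.fixture
def small_synthetic():
    """A 40 x 120 generated fixture with planted truth, preprocessed."""
    truth = generate_dataset(
        SyntheticSpec(n_samples=40, n_genes=120, n_informative=5,
                      n_near_constant=10, seed=11)
    )
    return truth, preprocess(truth.dataset)
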