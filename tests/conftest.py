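import numpy as np
import pytest

from rfdcriteria.datasets import ChemicalRecord, DescriptorTable, build_dataset
from rfdcriteria.synthetic import SyntheticSpec, generate_descriptor_matrix, generate_response


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A well-conditioned 30x5 table with no degenerate columns."""
    values = rng.normal(size=(30, 5))
    ids = [f"c{i}" for i in range(30)]
    return DescriptorTable(ids, [f"D{j}" for j in range(5)], values)


def make_dataset(n=60, p=6, coefs=None, intercept=1.0, noise_sd=0.0, seed=0,
                 train_fraction=0.75):
    """Synthetic ModelingDataset built through the public generators."""
    coefs = coefs if coefs is not None else {}
    spec = SyntheticSpec(
        n_chemicals=n, n_descriptors=p, true_coefficients=coefs,
        intercept=intercept, noise_sd=noise_sd, seed=seed,
    )
    table = generate_descriptor_matrix(spec)
    responses = generate_response(table, spec)
    return build_dataset(table, responses, train_fraction=train_fraction, seed=seed)
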