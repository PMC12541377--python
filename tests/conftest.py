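import numpy as np
import pytest

from nucshift import ChromatinModel


@pytest.fixture(scope="session")
def small_model() -> ChromatinModel:
    """A 40-gene, 2 x 200 kb genome; enough rows for metagene statistics."""
    return ChromatinModel(n_genes=40)


@pytest.fixture(scope="session")
def shifted_model(small_model) -> ChromatinModel:
    """small_model with a uniform -25 bp +1 shift planted in '+rap'."""
    genes = small_model.layout()["gene_id"]
    return small_model.with_condition("+rap", {g: -25 for g in genes})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.Philox(20260921))
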