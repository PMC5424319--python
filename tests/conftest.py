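import logging

import pytest

from codonpairs import CodonPairSet, GeneratorConfig, generate_genes, generate_expression
from codonpairs.synthetic_data import default_weight_table

logging.getLogger("codonpairs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pairs():
    return CodonPairSet()


@pytest.fixture(scope="session")
def weights():
    return default_weight_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene synthetic dataset with the default planted effects."""
    config = GeneratorConfig(n_genes=300, length_median=150.0)
    records, truth = generate_genes(config, seed=11)
    expression = generate_expression(truth, config, seed=11)
    return records, truth, expression, config
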