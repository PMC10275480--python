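import numpy as np
import pytest

from paralogdiv import (SyntheticSpec, generate_gene_table, generate_paralog_pairs,
                        pair_divergence_table)


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def dataset(synth_spec):
    """Gene table with imprinted paralog pairs plus ground truth."""
    genes = generate_gene_table(synth_spec)
    genes, pairs, truth = generate_paralog_pairs(synth_spec, genes)
    return genes, pairs, truth


@pytest.fixture(scope="session")
def genes(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def pairs(dataset):
    return dataset[1]


@pytest.fixture(scope="session")
def truth(dataset):
    return dataset[2]


@pytest.fixture(scope="session")
def divergence_table(genes, pairs):
    return pair_divergence_table(genes, pairs)


@pytest.fixture(scope="session")
def reference(divergence_table):
    return {k: divergence_table[k].to_numpy(float)
            for k in ("fc_bm", "fc_bp", "fc_p")}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
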