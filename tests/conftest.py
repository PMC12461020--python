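import pandas as pd
import pytest

from omniarch import gene_sets
from omniarch.config import SyntheticConfig
from omniarch.synthetic import generate_all


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down universe that keeps every planted structure present."""
    return SyntheticConfig(
        n_genes=300, n_core=30, n_hsp=5, n_perturbagens=100,
        n_edges=600, n_snps=60, n_triples_per_class=20, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def small_classification(small_dataset):
    genes = small_dataset.genes
    scores = pd.Series(genes["consensus_score"].to_numpy(), index=genes["symbol"])
    omim = set(genes.loc[genes["is_omim"], "symbol"])
    return gene_sets.classify_genes(scores, omim)
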