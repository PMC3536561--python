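import pytest

from estsnp.synthetic_data import (
    SimConfig,
    simulate_est_alignments,
    simulate_gene_set,
    simulate_genotype_panel,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_loci=300, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_gene_set(small_config)


@pytest.fixture(scope="session")
def small_alignments(small_truth):
    alignments, labels = simulate_est_alignments(small_truth)
    return alignments, labels


@pytest.fixture(scope="session")
def small_panel(small_truth):
    matrix, manifest, truth_table = simulate_genotype_panel(small_truth)
    return matrix, manifest, truth_table
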