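import numpy as np
import pytest

import dgsl


@pytest.fixture(scope="session")
def small_data():
    """Small planted-cluster dataset shared by training/evaluation tests."""
    return dgsl.generate(dgsl.SyntheticConfig(m=40, n=50, n_clusters=3, seed=11))


@pytest.fixture(scope="session")
def small_graphs(small_data):
    gd = dgsl.topk_neighbor_graph(dgsl.build_similarity_matrix(small_data.disease_annotations), 5)
    gg = dgsl.topk_neighbor_graph(dgsl.build_similarity_matrix(small_data.gene_annotations), 5)
    return gd, gg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
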