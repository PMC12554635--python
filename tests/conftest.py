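import warnings

import numpy as np
import pytest

from exprnet.cluster import CandidateCluster
from exprnet.datasets import generate_paired, generate_unpaired


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # the pipeline legitimately warns (fallbacks, empty subgraphs); tests
    # assert on warnings explicitly where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def planted_unpaired():
    return generate_unpaired(n_genes=60, n_per_class=25, n_markers=10,
                             effect_size=2.0, dispersion=0.3, seed=11)


@pytest.fixture
def planted_paired():
    return generate_paired(n_genes=40, n_pairs=15, n_markers=8,
                           effect_size=1.5, subject_sd=0.5, seed=12)


def make_cluster(gene, members, median=0.0, size=None, level=1, node_id=0):
    members = frozenset(members)
    return CandidateCluster(gene_id=gene, members=members,
                            median_value=float(median),
                            size=size or len(members), tree_level=level,
                            node_id=node_id)


@pytest.fixture
def toy_clusters():
    """Three genes with hand-chosen sample memberships."""
    return {
        "gA": [make_cluster("gA", {"s1", "s2"}, median=1.0, node_id=5)],
        "gB": [make_cluster("gB", {"s2", "s3"}, median=-1.0, node_id=6)],
        "gC": [make_cluster("gC", {"s4"}, median=2.0, node_id=7)],
    }


def random_cluster_collection(rng, n_genes=8, n_samples=12, max_clusters=4):
    """Random memberships for oracle comparisons."""
    samples = [f"s{i}" for i in range(n_samples)]
    out = {}
    for g in range(n_genes):
        gene = f"g{g}"
        clusters = []
        for c in range(rng.integers(1, max_clusters + 1)):
            size = int(rng.integers(1, n_samples))
            members = rng.choice(samples, size=size, replace=False)
            clusters.append(make_cluster(gene, set(members),
                                         median=float(rng.normal()),
                                         node_id=100 + c))
        out[gene] = clusters
    return out
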