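import numpy as np
import pytest

from bgcevo.model import DomainAnnotation, Gene, GeneCluster, assign_order_index
from bgcevo.simulate import random_dna, translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cluster(cluster_id, organism_id, seq_or_len, gene_specs=None,
                 rng=None):
    """Small nucleotide-space cluster for tests.

    ``gene_specs``: list of (start, end) pairs; a gene's protein is
    translated from the sequence, one domain per gene covering aa [0, 20).
    """
    if isinstance(seq_or_len, int):
        seq = random_dna(rng or np.random.default_rng(0), seq_or_len)
    else:
        seq = seq_or_len
    if gene_specs is None:
        gene_specs = [(0, len(seq) - len(seq) % 3)]
    genes, domains = [], []
    for i, (s, e) in enumerate(gene_specs):
        prot = translate(seq[s:e])
        gid = f"{cluster_id}_g{i}"
        genes.append(Gene(gid, s, e, 1, prot))
        domains.append(DomainAnnotation(
            domain_id=f"{cluster_id}_d{i}", pfam_id=f"PF{i:05d}",
            gene_id=gid, order_index=0, aa_seq=prot[:20],
            aa_start=0, aa_end=20))
    return GeneCluster(cluster_id=cluster_id, organism_id=organism_id,
                       genes=genes,
                       domains=assign_order_index(genes, domains),
                       sequence=seq)


def protein_cluster(cluster_id, organism_id, domain_seqs):
    from bgcevo.scenarios import _protein_cluster

    return _protein_cluster(cluster_id, organism_id, domain_seqs)


@pytest.fixture
def make_cluster_fixture():
    return make_cluster
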