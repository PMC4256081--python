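"""Neighbor joining, cluster-specific branching, column entropy."""

import random

import dendropy
import numpy as np
import pytest
from dendropy.simulate import treesim

from bgcevo.trees import (
    bgc_specificity,
    column_entropy,
    domain_distance_matrix,
    nj_tree,
    read_phylip,
    tree_from_newick,
    tree_to_newick,
    write_phylip,
)


def random_additive_instance(n, seed):
    rng = random.Random(seed)
    t = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                 num_extant_tips=n, rng=rng)
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = rng.uniform(0.05, 1.0)
    labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    pdm = t.phylogenetic_distance_matrix()
    tx = {x.label: x for x in t.taxon_namespace}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tx[labels[i]],
                                                       tx[labels[j]])
    return d, labels


def patristic(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {x.label: x for x in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tx[labels[i]],
                                                       tx[labels[j]])
    return d


def test_three_taxa_closed_form_branch_lengths():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(d, ["a", "b", "c"])
    lengths = {lf.taxon.label: lf.edge.length
               for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


@pytest.mark.parametrize("n", [4, 6, 8, 12])
def test_nj_recovers_additive_matrices_exactly(n):
    for seed in range(5):
        d, labels = random_additive_instance(n, seed * 31 + n)
        est = nj_tree(d, labels)
        assert np.allclose(patristic(est, labels), d, atol=1e-9)


def test_nj_agrees_with_independent_implementation():
    import skbio

    for seed in (1, 2, 3):
        d, labels = random_additive_instance(8, seed)
        ours = nj_tree(d, labels)
        other = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ours_skbio = skbio.TreeNode.read([tree_to_newick(ours)])
        assert ours_skbio.compare_rfd(other) == 0.0


def test_nj_rejects_asymmetry_and_small_matrices():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0.0]]),
                list("abc"))
    with pytest.raises(ValueError, match=">= 3"):
        nj_tree(np.zeros((2, 2)), list("ab"))


def test_tie_break_is_deterministic():
    # ultrametric 4-taxon matrix with two equally good joins
    d = np.array([
        [0.0, 0.2, 0.6, 0.6],
        [0.2, 0.0, 0.6, 0.6],
        [0.6, 0.6, 0.0, 0.2],
        [0.6, 0.6, 0.2, 0.0],
    ])
    t1 = tree_to_newick(nj_tree(d, list("abcd")))
    t2 = tree_to_newick(nj_tree(d, list("abcd")))
    assert t1 == t2


def test_negative_branch_lengths_clamped_with_warning():
    # non-additive matrix whose final three-way join goes negative
    d = np.array([
        [0.0, 0.862, 0.638, 0.356],
        [0.862, 0.0, 0.588, 0.216],
        [0.638, 0.588, 0.0, 0.118],
        [0.356, 0.216, 0.118, 0.0],
    ])
    with pytest.warns(UserWarning, match="clamped"):
        tree = nj_tree(d, list("abcd"))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            assert e.length >= 0


def test_domain_distance_matrix_is_identity_complement(rng):
    from tests.conftest import AA20, protein_cluster

    seq = "".join(rng.choice(list(AA20), 40))
    c = protein_cluster("c", "o", [("P", seq), ("P", seq), ("P", seq)])
    m, labels = domain_distance_matrix(c.domains_in_order())
    assert np.allclose(m, 0.0)
    with pytest.raises(ValueError, match=">= 3"):
        domain_distance_matrix(c.domains_in_order()[:2])


def test_specificity_two_cherries_is_one_and_monophyletic():
    d = np.array([
        [0.0, 0.1, 0.9, 0.9],
        [0.1, 0.0, 0.9, 0.9],
        [0.9, 0.9, 0.0, 0.1],
        [0.9, 0.9, 0.1, 0.0],
    ])
    tree = nj_tree(d, ["c1x", "c1y", "c2x", "c2y"])
    spec = bgc_specificity(tree, {"c1x": "c1", "c1y": "c1",
                                  "c2x": "c2", "c2y": "c2"})
    assert spec.overall_fraction == 1.0
    assert spec.per_cluster_monophyly == {"c1": True, "c2": True}


def test_specificity_interleaved_clusters_is_zero():
    # each leaf's closest neighbor belongs to the other cluster
    d = np.array([
        [0.0, 0.1, 0.9, 0.9],
        [0.1, 0.0, 0.9, 0.9],
        [0.9, 0.9, 0.0, 0.1],
        [0.9, 0.9, 0.1, 0.0],
    ])
    tree = nj_tree(d, ["c1x", "c2x", "c1y", "c2y"])
    spec = bgc_specificity(tree, {"c1x": "c1", "c2x": "c2",
                                  "c1y": "c1", "c2y": "c2"})
    assert spec.overall_fraction == 0.0


def test_specificity_invariant_to_uniform_scaling():
    d, labels = random_additive_instance(8, 5)
    cluster_of = {lb: f"cl{i % 2}" for i, lb in enumerate(labels)}
    s1 = bgc_specificity(nj_tree(d, labels), cluster_of)
    s2 = bgc_specificity(nj_tree(d * 7.5, labels), cluster_of)
    assert s1.overall_fraction == s2.overall_fraction
    assert s1.per_cluster_monophyly == s2.per_cluster_monophyly


def test_specificity_single_cluster_is_undefined():
    d, labels = random_additive_instance(5, 2)
    with pytest.raises(ValueError, match="single-cluster"):
        bgc_specificity(nj_tree(d, labels), {lb: "only" for lb in labels})


def test_entropy_closed_forms():
    ent, _ = column_entropy(["A", "A", "A", "A"])
    assert ent[0] == pytest.approx(0.0)
    ent, _ = column_entropy(["A", "A", "V", "V"])
    assert ent[0] == pytest.approx(1.0)
    ent, _ = column_entropy([c for c in "ACDEFGHIKLMNPQRSTVWY"])
    assert ent[0] == pytest.approx(np.log2(20))


def test_entropy_bounds_and_row_permutation_invariance(rng):
    rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY-"), 30))
            for _ in range(10)]
    ent1, flags1 = column_entropy(rows)
    perm = list(rng.permutation(10))
    ent2, flags2 = column_entropy([rows[i] for i in perm])
    valid = ~np.isnan(ent1)
    assert np.allclose(ent1[valid], ent2[valid])
    assert (ent1[valid] >= 0).all() and (ent1[valid] <= np.log2(20)).all()
    assert (flags1 == flags2).all()


def test_gap_rich_columns_flagged():
    ent, flags = column_entropy(["A-", "A-", "A-", "AV"])
    assert not flags[0] and flags[1]


def test_newick_roundtrip_preserves_patristic_distances():
    d, labels = random_additive_instance(6, 9)
    tree = nj_tree(d, labels)
    back = tree_from_newick(tree_to_newick(tree))
    assert np.allclose(patristic(back, labels), d, atol=1e-6)


def test_phylip_roundtrip():
    d, labels = random_additive_instance(5, 3)
    text = write_phylip(d, labels)
    d2, labels2 = read_phylip(text)
    assert labels2 == labels
    assert np.allclose(d2, d, atol=1e-6)
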