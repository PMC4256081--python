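"""Evolutionary-mode features: empirical p-values, ISI, VEI, network
topology, PCA."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bgcevo.modes import (
    CorpusDomainIndex,
    InternalHomology,
    _empirical_upper_p,
    domain_network_features,
    feature_table,
    internal_background,
    internal_homology,
    internal_similarity_index,
    pca,
    vertical_evolution_index,
    within_cluster_best_identities,
)
from tests.conftest import AA20, protein_cluster


def test_empirical_p_above_all_background_is_one_over_n_plus_1():
    bg = np.sort(np.linspace(10, 90, 99))
    assert _empirical_upper_p(bg, 95.0) == pytest.approx(1 / 100)


def test_empirical_p_below_all_background_is_one():
    bg = np.sort(np.linspace(10, 90, 99))
    assert _empirical_upper_p(bg, 5.0) == 1.0


def test_single_same_type_domain_is_undefined(rng):
    c = protein_cluster("c", "o", [("PKS_KS", "".join(rng.choice(list(AA20), 30)))])
    assert within_cluster_best_identities(c) == {}
    assert internal_homology(c, {}) == []
    assert internal_similarity_index([]) is None


def test_isi_is_zero_when_all_p_equal_one():
    h = [InternalHomology(f"d{i}", 10.0, 1.0) for i in range(3)]
    assert internal_similarity_index(h) == 0.0


def test_isi_arithmetic_under_one_minus_p():
    h = [InternalHomology("d1", 99.0, 0.01),
         InternalHomology("d2", 95.0, 0.05),
         InternalHomology("d3", 90.0, 0.10)]
    assert internal_similarity_index(h) == pytest.approx((0.99 + 0.95 + 0.90) / 3)


def test_isi_invariant_under_domain_relabeling(rng):
    seqs = ["".join(rng.choice(list(AA20), 30)) for _ in range(4)]
    c1 = protein_cluster("c1", "o", [("PX", s) for s in seqs])
    c2 = protein_cluster("c2", "o", [("PX", s) for s in reversed(seqs)])
    bg = internal_background([c1])
    isi1 = internal_similarity_index(internal_homology(c1, bg))
    isi2 = internal_similarity_index(internal_homology(c2, bg))
    assert isi1 == pytest.approx(isi2)


def test_adding_unrelated_type_leaves_existing_p_unchanged(rng):
    seqs = ["".join(rng.choice(list(AA20), 30)) for _ in range(3)]
    base = protein_cluster("c", "o", [("PX", s) for s in seqs])
    extended = protein_cluster(
        "c", "o", [("PX", s) for s in seqs]
        + [("PY", "".join(rng.choice(list(AA20), 30)))])
    bg = internal_background([base])
    p1 = {h.domain_id[-1]: h.p_internal for h in internal_homology(base, bg)}
    bg2 = internal_background([extended])
    p2 = {h.domain_id[-1]: h.p_internal
          for h in internal_homology(extended, bg2)}
    for k in p1:
        assert p1[k] == pytest.approx(p2[k])


# ---------------------------------------------------------------------------
# VEI


@pytest.mark.parametrize("kind,check", [
    ("positive", lambda v: v > 0.1),
    ("negative", lambda v: v < -0.1),
])
def test_vei_sign_on_constructed_corpora(kind, check):
    from bgcevo.scenarios import robust_mean_identity_similarity, vei_corpus

    corpus, focal = vei_corpus(kind, 5)
    idx = CorpusDomainIndex(
        corpus, cluster_similarity_fn=robust_mean_identity_similarity)
    veis = [vertical_evolution_index(c, idx) for c in corpus
            if c.cluster_id in focal]
    assert check(float(np.mean([v for v in veis if v is not None])))


def test_vei_near_zero_on_exchangeable_corpus():
    from bgcevo.scenarios import robust_mean_identity_similarity, vei_corpus

    means = []
    for seed in range(20):
        corpus, focal = vei_corpus("null", seed)
        idx = CorpusDomainIndex(
            corpus, cluster_similarity_fn=robust_mean_identity_similarity)
        veis = [vertical_evolution_index(c, idx) for c in corpus]
        means.append(float(np.mean([v for v in veis if v is not None])))
    assert abs(np.mean(means)) < 0.1


def test_vei_requires_three_clusters(rng):
    c = protein_cluster("a", "o", [("P", "".join(rng.choice(list(AA20), 30)))])
    idx = CorpusDomainIndex([c], cluster_similarity_fn=lambda a, b: 0.0)
    with pytest.raises(ValueError, match=">= 3"):
        vertical_evolution_index(c, idx)


# ---------------------------------------------------------------------------
# network topology


def test_three_mutually_similar_domains_form_a_triangle(rng):
    seq = "".join(rng.choice(list(AA20), 40))
    c = protein_cluster("c", "o", [("P", seq), ("P", seq), ("P", seq)])
    f = domain_network_features(c)
    assert f["graph_transitivity"] == 1.0
    assert f["n_cliques_3"] == 1
    assert f["n_connected_components_50"] == 1


def test_no_edges_above_threshold_gives_singleton_components(rng):
    doms = [("P", "".join(rng.choice(list(AA20), 40))) for _ in range(4)]
    c = protein_cluster("c", "o", doms)
    f = domain_network_features(c)
    assert f["n_connected_components_50"] == 4
    assert f["n_cliques_2"] == 0 and f["n_cliques_3"] == 0
    assert f["n_cliques_4"] == 0


def test_topology_features_match_graph_enumeration(rng):
    # six domains in two similar triplets
    s1 = "".join(rng.choice(list(AA20), 40))
    s2 = "".join(rng.choice(list(AA20), 40))
    def jitter(s, k):
        out = list(s)
        for pos in rng.choice(len(out), k, replace=False):
            out[pos] = rng.choice([c for c in AA20 if c != out[pos]])
        return "".join(out)
    doms = [("P", jitter(s1, 3)) for _ in range(3)] + \
        [("P", jitter(s2, 3)) for _ in range(3)]
    c = protein_cluster("c", "o", doms)
    f = domain_network_features(c)
    from bgcevo.align import global_identity

    g = nx.Graph()
    g.add_nodes_from(range(6))
    seqs = [d.aa_seq for d in c.domains_in_order()]
    for i, j in combinations(range(6), 2):
        if global_identity(seqs[i], seqs[j]) > 50:
            g.add_edge(i, j)
    assert f["n_cliques_2"] == g.number_of_edges()
    triangles = sum(1 for nodes in combinations(g, 3)
                    if all(g.has_edge(a, b)
                           for a, b in combinations(nodes, 2)))
    assert f["n_cliques_3"] == triangles
    assert f["n_connected_components_50"] == \
        nx.number_connected_components(g)
    assert f["graph_transitivity"] == pytest.approx(nx.transitivity(g))


# ---------------------------------------------------------------------------
# PCA


def test_perfectly_correlated_features_give_one_component(rng):
    x = rng.normal(size=20)
    df = pd.DataFrame({"f1": x, "f2": 2 * x + 3})
    res = pca(df)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_variance_ratios_sum_to_one(rng):
    df = pd.DataFrame(rng.normal(size=(15, 5)),
                      columns=[f"f{i}" for i in range(5)])
    res = pca(df)
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)


def test_scores_match_svd_oracle_up_to_sign(rng):
    vals = rng.normal(size=(10, 5))
    df = pd.DataFrame(vals, columns=[f"f{i}" for i in range(5)])
    res = pca(df, standardize=True)
    z = (vals - vals.mean(0)) / vals.std(0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    oracle = u * s
    for k in range(5):
        got = res.scores.iloc[:, k].to_numpy()
        assert (np.allclose(got, oracle[:, k], atol=1e-8)
                or np.allclose(got, -oracle[:, k], atol=1e-8))


def test_constant_feature_column_dropped_with_warning(rng):
    df = pd.DataFrame({"f1": rng.normal(size=10),
                       "f2": rng.normal(size=10),
                       "f3": np.ones(10)})
    with pytest.warns(UserWarning, match="constant"):
        res = pca(df)
    assert "f3" not in res.loadings.columns


def test_feature_table_has_all_named_features():
    from bgcevo.modes import FEATURE_NAMES
    from bgcevo.scenarios import simulate_isi_corpus

    corpus, _labels = simulate_isi_corpus(0, 4, 4)
    ft = feature_table(corpus)
    assert list(ft.columns) == FEATURE_NAMES
    assert len(ft) == 8
    assert np.isfinite(ft.to_numpy()).all()
    assert ((ft["internal_similarity_index"] >= 0)
            & (ft["internal_similarity_index"] <= 1)).all()
    assert ((ft["vertical_evolution_index"] >= -1)
            & (ft["vertical_evolution_index"] <= 1)).all()
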