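"""Similarity indices, operon calling, organism dereplication."""

import numpy as np
import pytest

from bgcevo.align import global_identity
from bgcevo.model import Fingerprint, OrganismDistanceTable
from bgcevo.similarity import (
    HIS_PFAMS,
    bgc_jaccard,
    besthit_organism_distances,
    dereplicate_organisms,
    domain_identity_background,
    find_operons,
    markov_cluster,
    tanimoto,
)
from tests.conftest import AA20, protein_cluster


def rand_aa(rng, n=40):
    return "".join(rng.choice(list(AA20), n))


def mutate(seq, k, rng):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([c for c in AA20 if c != s[pos]])
    return "".join(s)


@pytest.fixture
def family_corpus(rng):
    """Three related clusters plus one Pfam-disjoint outsider."""
    src = [(f"P{j}", rand_aa(rng)) for j in range(4)]
    corpus = [
        protein_cluster(f"c{i}", f"org{i}",
                        [(p, mutate(s, 2 + 3 * i, rng)) for p, s in src])
        for i in range(3)
    ]
    corpus.append(protein_cluster("out", "orgX",
                                  [(f"Q{j}", rand_aa(rng)) for j in range(4)]))
    return corpus


def test_background_counts_same_pfam_cross_cluster_pairs(family_corpus):
    bg = domain_identity_background(family_corpus)
    # P0 occurs in 3 clusters -> 3 cross-cluster pairs
    assert len(bg.per_pfam["P0"]) == 3
    # the outsider's Pfams occur once each -> excluded
    assert "Q0" in bg.excluded


def test_percentile_threshold_equals_sort_oracle(rng):
    corpus = [
        protein_cluster(f"c{i}", f"o{i}", [("PX", rand_aa(rng))])
        for i in range(30)
    ]
    bg = domain_identity_background(corpus)
    dist = bg.per_pfam["PX"]
    assert bg.threshold("PX") == pytest.approx(np.percentile(np.sort(dist), 90))


def test_upper_tail_p_at_maximum_is_small_not_zero(family_corpus):
    bg = domain_identity_background(family_corpus)
    p = bg.upper_tail_p("P0", 100.0)
    n = len(bg.pooled)  # sparse family falls back to the pooled distribution
    assert 0 < p <= 1 / (n / 2)


def test_jaccard_is_1_for_identical_and_0_for_disjoint(family_corpus, rng):
    doms = [(f"P{j}", rand_aa(rng)) for j in range(6)]
    a = protein_cluster("a", "o1", doms)
    b = protein_cluster("b", "o2", doms)
    other = protein_cluster("z", "o3", [(f"R{j}", rand_aa(rng))
                                        for j in range(6)])
    bg = domain_identity_background(family_corpus + [a, b, other])
    assert bgc_jaccard(a, b, bg).jaccard == 1.0
    assert bgc_jaccard(a, other, bg).jaccard == 0.0
    assert bgc_jaccard(a, b, bg).jaccard == bgc_jaccard(b, a, bg).jaccard


def test_jaccard_partial_overlap_denominator_convention(rng):
    # a = {P1, P2}, b = {P1, P3}; only the P1 pair can match
    shared = rand_aa(rng)
    a = protein_cluster("a", "o1", [("P1", shared), ("P2", rand_aa(rng))])
    b = protein_cluster("b", "o2", [("P1", shared), ("P3", rand_aa(rng))])
    # background P1 pairs mostly diverged, so the identical pair clears it
    extra = [protein_cluster(f"e{i}", f"oe{i}", [("P1", rand_aa(rng))])
             for i in range(8)]
    bg = domain_identity_background([a, b] + extra)
    s = bgc_jaccard(a, b, bg)
    assert s.n_top_pairs == 1
    assert s.jaccard == pytest.approx(1 / (2 + 2 - 1))


def test_tanimoto_popcount_arithmetic():
    a = Fingerprint((1, 1, 0, 0), 4)
    b = Fingerprint((1, 0, 1, 0), 4)
    assert tanimoto(a, b) == pytest.approx(1 / 3)
    assert tanimoto(a, a) == 1.0
    assert tanimoto(a, Fingerprint((0, 0, 1, 1), 4)) == 0.0
    with pytest.raises(ValueError, match="all-zero"):
        tanimoto(Fingerprint((0, 0, 0, 0), 4), Fingerprint((0, 0, 0, 0), 4))


def test_tanimoto_matches_numpy_popcounts(rng):
    for _ in range(20):
        av = rng.integers(0, 2, 16)
        bv = rng.integers(0, 2, 16)
        if not (av | bv).any():
            continue
        expected = (av & bv).sum() / (av | bv).sum()
        assert tanimoto(Fingerprint(tuple(av), 16),
                        Fingerprint(tuple(bv), 16)) == pytest.approx(expected)


def test_besthit_distances_concentrate_at_sister_distance(rng):
    # orgA and orgB are sisters (distance 0.1), orgC is distant (0.9)
    doms = [(f"P{j}", rand_aa(rng)) for j in range(3)]
    corpus = [
        protein_cluster("a", "orgA", [(p, s) for p, s in doms]),
        protein_cluster("b", "orgB", [(p, mutate(s, 2, rng))
                                      for p, s in doms]),
        protein_cluster("c", "orgC", [(p, mutate(s, 20, rng))
                                      for p, s in doms]),
    ]
    table = OrganismDistanceTable(
        ["orgA", "orgB", "orgC"],
        np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]))
    dists, background, skipped = besthit_organism_distances(corpus, table)
    assert skipped == 0
    # a and b hit each other; c hits its closest which is a or b
    assert (dists[:6] == 0.1).all()
    assert len(background) == 3


def test_single_organism_corpus_skips_every_domain(rng):
    corpus = [protein_cluster("a", "solo", [("P1", rand_aa(rng))]),
              protein_cluster("b", "solo", [("P1", rand_aa(rng))])]
    table = OrganismDistanceTable(["solo"], np.zeros((1, 1)))
    dists, _bg, skipped = besthit_organism_distances(corpus, table)
    assert len(dists) == 0 and skipped == 2


def test_hgt_corpus_has_larger_besthit_distances_than_vertical():
    from bgcevo.scenarios import hgt_and_vertical_corpora

    (vc, _l1, _n1, vd), (hc, _l2, _n2, hd) = hgt_and_vertical_corpora(11)
    dv, _b1, _s1 = besthit_organism_distances(vc, vd)
    dh, _b2, _s2 = besthit_organism_distances(hc, hd)
    assert dh.mean() > dv.mean()


# ---------------------------------------------------------------------------
# operon calling


def test_adjacent_pathway_domains_with_one_confident_hit_is_one_call():
    rows = [("o1", "g1", "PF00475", 0.6), ("o1", "g2", "PF00815", 0.4)]
    calls = find_operons(rows, HIS_PFAMS)
    assert len(calls) == 1
    assert calls[0].max_probability == 0.6


def test_single_pathway_domain_is_not_an_operon():
    assert find_operons([("o1", "g1", "PF00475", 0.9)], HIS_PFAMS) == []


def test_two_low_probability_domains_are_not_an_operon():
    rows = [("o1", "g1", "PF00475", 0.3), ("o1", "g2", "PF00815", 0.4)]
    assert find_operons(rows, HIS_PFAMS) == []


def test_gap_of_more_than_one_gene_splits_runs():
    rows = [("o1", "g1", "PF00475", 0.9),
            ("o1", "g2", "PFXXXXX", 0.1),
            ("o1", "g3", "PFYYYYY", 0.1),
            ("o1", "g4", "PF00815", 0.9)]
    assert find_operons(rows, HIS_PFAMS) == []


# ---------------------------------------------------------------------------
# Markov clustering / dereplication


def test_disconnected_groups_stay_separate():
    mi = {}
    for group in (["a1", "a2", "a3"], ["b1", "b2"]):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                mi[(group[i], group[j])] = [100.0]
    mi[("a1", "b1")] = [0.0]
    reps, clusters = dereplicate_organisms(mi)
    assert reps == ["a1", "b1"]
    assert clusters == [["a1", "a2", "a3"], ["b1", "b2"]]


def test_single_organism_is_its_own_representative():
    reps, clusters = dereplicate_organisms({("x", "x"): [100.0]})
    assert reps == ["x"] and clusters == [["x"]]


def test_mutually_dissimilar_organisms_each_kept():
    orgs = ["o1", "o2", "o3", "o4"]
    mi = {(a, b): [0.0] for i, a in enumerate(orgs)
          for b in orgs[i + 1:]}
    reps, clusters = dereplicate_organisms(mi)
    assert reps == orgs
    assert all(len(c) == 1 for c in clusters)


def test_markov_clustering_output_is_a_partition(rng):
    n = 12
    sim = rng.uniform(0, 1, (n, n))
    sim = (sim + sim.T) / 2
    np.fill_diagonal(sim, 0)
    clusters = markov_cluster(sim)
    flat = [i for c in clusters for i in c]
    assert sorted(flat) == list(range(n))


def test_jaccard_and_tanimoto_positively_coupled_on_family():
    from scipy.stats import spearmanr

    from bgcevo.scenarios import coupled_family_with_fingerprints

    rhos = []
    for seed in (3, 11, 29):
        corpus, fps = coupled_family_with_fingerprints(seed)
        bg = domain_identity_background(corpus)
        ref = corpus[0]
        jac = [bgc_jaccard(ref, c, bg).jaccard for c in corpus[1:]]
        tan = [tanimoto(fps[ref.cluster_id], fps[c.cluster_id])
               for c in corpus[1:]]
        rho, _p = spearmanr(jac, tan)
        rhos.append(rho)
    assert all(r > 0 for r in rhos)


def test_non_symmetric_marker_table_is_fatal():
    with pytest.raises(ValueError, match="symmetric"):
        dereplicate_organisms({("a", "b"): [90.0], ("b", "a"): [10.0]})
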