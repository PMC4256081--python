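"""Phylogenetic-profiling oracles: identity matrices, correlations, motif
extraction and the χ² significance rule."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from bgcevo.align import global_identity
from bgcevo.profiling import (
    DomainOrganismMatrix,
    build_identity_matrix,
    chi2_equal_counts,
    correlate_and_reorder,
    extract_motifs,
    motif_occurs,
    profile_corpus,
    test_motif_significance,
)
from tests.conftest import AA20, protein_cluster


def rand_doms(rng, pfams, n=30):
    return [(p, "".join(rng.choice(list(AA20), n))) for p in pfams]


def test_single_organism_corpus_gives_all_zero_matrix(rng):
    c = protein_cluster("c1", "solo", rand_doms(rng, ["P1", "P2"]))
    m = build_identity_matrix(c, [c], ["solo"])
    assert (m.values == 0).all()


def test_exact_copy_organism_gives_column_of_100(rng):
    doms = rand_doms(rng, ["P1", "P2", "P3"])
    c1 = protein_cluster("c1", "orgA", doms)
    c2 = protein_cluster("c2", "orgB", doms)
    m = build_identity_matrix(c1, [c1, c2], ["orgA", "orgB"])
    col = m.values[:, m.organism_ids.index("orgB")]
    assert (col == 100.0).all()


def test_identity_matrix_equals_brute_force_max(rng):
    corpus = [
        protein_cluster(f"c{i}", f"org{i % 4}",
                        rand_doms(rng, ["P1", "P2", "P3"]))
        for i in range(6)
    ]
    organisms = sorted({c.organism_id for c in corpus})
    target = corpus[0]
    m = build_identity_matrix(target, corpus, organisms)
    for i, d in enumerate(target.domains_in_order()):
        for j, org in enumerate(organisms):
            expected = 0.0
            for c in corpus:
                if c.cluster_id == target.cluster_id or c.organism_id != org:
                    continue
                for d2 in c.domains:
                    if d2.pfam_id == d.pfam_id:
                        expected = max(expected,
                                       global_identity(d.aa_seq, d2.aa_seq))
            assert m.values[i, j] == pytest.approx(expected)


def make_matrix(values, pfams=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    pfams = pfams or [f"P{i}" for i in range(n)]
    return DomainOrganismMatrix(
        "c", [f"d{i}" for i in range(n)], pfams,
        [f"o{j}" for j in range(values.shape[1])], values)


def test_identical_profiles_correlate_at_1_and_sit_adjacent():
    m = make_matrix([[10, 50, 90, 20], [10, 50, 90, 20], [90, 10, 20, 80]])
    corr, order = correlate_and_reorder(m)
    # the two identical rows must be adjacent after reordering
    pos = {orig: k for k, orig in enumerate(order)}
    assert abs(pos[0] - pos[1]) == 1
    assert corr[pos[0], pos[1]] == pytest.approx(1.0)


def test_negated_profile_correlates_at_minus_1():
    m = make_matrix([[10.0, 50, 90], [90.0, 50, 10]])
    corr, _ = correlate_and_reorder(m)
    assert corr[0, 1] == pytest.approx(-1.0)


def test_pearson_values_match_direct_formula(rng):
    vals = rng.uniform(0, 100, size=(5, 6))
    m = make_matrix(vals)
    corr, order = correlate_and_reorder(m)
    inv = {o: k for k, o in enumerate(order)}
    for i in range(5):
        for j in range(5):
            x, y = vals[i], vals[j]
            expected = (np.mean((x - x.mean()) * (y - y.mean()))
                        / (x.std() * y.std()))
            assert corr[inv[i], inv[j]] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_row_gets_correlation_zero():
    m = make_matrix([[50.0, 50, 50], [10.0, 60, 90]])
    corr, _ = correlate_and_reorder(m)
    assert corr[0, 1] == 0.0 and corr[0, 0] == 0.0


def test_fewer_than_two_organisms_is_an_error():
    m = make_matrix([[1.0], [2.0]])
    with pytest.raises(ValueError, match="organisms"):
        correlate_and_reorder(m)


def test_motif_runs_follow_stated_diagonal_rule():
    # adjacent-diagonal correlations 0.9, 0.8, 0.3, 0.7 over d1..d5
    n = 5
    corr = np.zeros((n, n))
    for k, v in enumerate([0.9, 0.8, 0.3, 0.7]):
        corr[k, k + 1] = corr[k + 1, k] = v
    pfams = [f"P{i + 1}" for i in range(n)]
    motifs = extract_motifs(corr, list(range(n)), pfams, cc_cutoff=0.5)
    assert set(motifs) == {("P1", "P2"), ("P2", "P3"), ("P1", "P2", "P3"),
                           ("P4", "P5")}
    stricter = extract_motifs(corr, list(range(n)), pfams, cc_cutoff=0.8)
    assert set(stricter) == {("P1", "P2")}
    nothing = extract_motifs(corr, list(range(n)), pfams, cc_cutoff=0.95)
    assert nothing == []


def test_chi2_null_by_symmetry():
    stat, p = chi2_equal_counts(10, 10)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi2_formula_and_tail_oracle():
    stat, p = chi2_equal_counts(40, 10)
    assert stat == pytest.approx(18.0)
    assert p == pytest.approx(chi2_dist.sf(18.0, 1), rel=1e-12)
    assert p == pytest.approx(2.2e-5, rel=0.05)


def test_bonferroni_factor_is_number_of_testable_motifs(rng):
    corpus = [
        protein_cluster(f"c{i}", f"org{i}", rand_doms(rng, ["PA", "PB"]))
        for i in range(5)
    ]
    candidates = {"c0": [("PA", "PB")]}
    results = test_motif_significance(candidates, corpus)
    assert len(results) == 1
    r = results[0]
    assert r.n_coevolving == 1 and r.n_possible_noncoevolving == 4
    assert r.p_bonferroni == pytest.approx(min(1.0, r.p * 1))


def test_motif_occurrence_is_order_insensitive_consecutive(rng):
    c = protein_cluster("c", "o", rand_doms(rng, ["PA", "PB", "PC", "PD"]))
    assert motif_occurs(c, ("PB", "PC"))
    assert motif_occurs(c, ("PC", "PB"))
    assert not motif_occurs(c, ("PA", "PC"))


def test_motif_extraction_invariant_to_organism_permutation(rng):
    vals = rng.uniform(0, 100, size=(4, 8))
    m1 = make_matrix(vals)
    perm = rng.permutation(8)
    m2 = make_matrix(vals[:, perm])
    c1, o1 = correlate_and_reorder(m1)
    c2, o2 = correlate_and_reorder(m2)
    motifs1 = extract_motifs(c1, o1, m1.pfam_ids, 0.3)
    motifs2 = extract_motifs(c2, o2, m2.pfam_ids, 0.3)
    assert sorted(motifs1) == sorted(motifs2)


def test_planted_cassette_recovered_significant():
    from bgcevo.scenarios import simulate_profiling_corpus
    from collections import Counter

    corpus, cassette = simulate_profiling_corpus(3)
    results, _cands = profile_corpus(corpus)
    target = frozenset(Counter(cassette).items())
    hits = [r for r in results
            if frozenset(Counter(r.pfam_ids).items()) == target]
    assert hits and min(r.p_bonferroni for r in hits) < 0.001
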