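"""Simulator contracts: determinism, null model, event semantics, replay."""

import itertools

import numpy as np
import pytest

from bgcevo.align import global_identity, reverse_complement
from bgcevo.simulate import (
    EventLogEntry,
    SimConfig,
    ancestral_clusters,
    apply_event,
    build_assembly_line,
    make_ancestral_cluster,
    replay_log,
    simulate_corpus,
)


def null_config(seed=0, **kw):
    return SimConfig(seed=seed, n_organisms=4, n_ancestral_clusters=1,
                     substitution_rate=0.0, **kw)


def test_null_model_tips_equal_ancestor_and_empty_log():
    cfg = null_config()
    corpus, log, _nwk, _dist = simulate_corpus(cfg)
    assert log == []
    anc = ancestral_clusters(cfg)["fam00"]
    assert len(corpus) == 4
    for tip in corpus:
        assert tip.sequence == anc.sequence
        assert [g.gene_id for g in tip.genes] == [g.gene_id for g in anc.genes]


def test_fixed_seed_runs_are_identical():
    cfg = SimConfig(seed=77, n_organisms=6, n_ancestral_clusters=2,
                    substitution_rate=0.02, indel_rate=0.3,
                    duplication_rate=0.2, inversion_rate=0.2,
                    nrps_pks_fraction=0.5, gene_conversion_rate=0.5)
    out1 = simulate_corpus(cfg)
    out2 = simulate_corpus(SimConfig(**vars(cfg)))
    assert [c.sequence for c in out1[0]] == [c.sequence for c in out2[0]]
    assert out1[2] == out2[2]
    assert [(e.event_type, e.span) for e in out1[1]] == \
        [(e.event_type, e.span) for e in out2[1]]


def test_negative_rate_rejected():
    with pytest.raises(ValueError, match="rates"):
        SimConfig(seed=0, indel_rate=-1.0).validate()


def test_deletion_only_regime_with_shrinking_expectation_rejected():
    cfg = SimConfig(seed=0, indel_rate=5.0, indel_insert_prob=0.0,
                    n_organisms=20, indel_size_kb=(4.0, 8.0))
    with pytest.raises(ValueError, match="length"):
        cfg.validate()


def test_indel_count_matches_poisson_expectation_over_seeds():
    lam = 0.4
    total = 0
    n_branches_total = 0
    for seed in range(20):
        cfg = SimConfig(seed=seed, n_organisms=6, n_ancestral_clusters=1,
                        substitution_rate=0.0, indel_rate=lam)
        _corpus, log, _nwk, _dist = simulate_corpus(cfg)
        total += sum(e.event_type == "indel" for e in log)
        n_branches_total += 2 * cfg.n_organisms - 2
    expected = lam * n_branches_total
    assert abs(total - expected) <= 3 * np.sqrt(expected)


def test_replay_log_reproduces_tips_exactly():
    cfg = SimConfig(seed=5, n_organisms=6, n_ancestral_clusters=2,
                    substitution_rate=0.02, indel_rate=0.4,
                    duplication_rate=0.3, inversion_rate=0.3,
                    transfer_rate=0.3, nrps_pks_fraction=0.5,
                    module_duplication_rate=0.2, gene_conversion_rate=0.5)
    corpus, log, newick, _dist = simulate_corpus(cfg)
    tips = replay_log(ancestral_clusters(cfg), log, newick)
    assert len(tips) == len(corpus)
    for a, b in zip(corpus, tips):
        assert a.cluster_id == b.cluster_id
        assert a.sequence == b.sequence
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]


def test_distance_table_normalized_with_zero_diagonal():
    _c, _l, _n, dist = simulate_corpus(null_config())
    assert dist.distances.max() == pytest.approx(1.0)
    assert np.allclose(np.diag(dist.distances), 0.0)


# ---------------------------------------------------------------------------
# apply_event semantics


@pytest.fixture
def base_cluster(rng):
    cfg = SimConfig(seed=9, genes_per_cluster=(8, 8), gene_length=(900, 1200))
    return make_ancestral_cluster(cfg, rng, "base")


def test_inversion_preserves_length_and_reverse_complements_span(base_cluster):
    c = base_cluster
    s, e = c.genes[2].start, c.genes[4].end
    entry = EventLogEntry("inversion", ("p", "q"), c.cluster_id, (s, e),
                          (e - s) / 1000.0)
    out = apply_event(c, entry)
    assert out.length == c.length
    assert out.sequence[s:e] == reverse_complement(c.sequence[s:e])
    assert out.sequence[:s] == c.sequence[:s]
    inverted = [g for g in out.genes if s <= g.start and g.end <= e]
    assert all(g.strand == -1 for g in inverted)
    # proteins are conserved (translated from the flipped strand)
    assert {g.protein for g in inverted} == \
        {g.protein for g in c.genes if s <= g.start and g.end <= e}


def test_duplication_adds_span_length_and_gene_count(base_cluster):
    c = base_cluster
    s, e = c.genes[1].start, c.genes[2].end
    entry = EventLogEntry("duplication", ("p", "q"), c.cluster_id, (s, e),
                          (e - s) / 1000.0, payload={"suffix": "_dup"})
    out = apply_event(c, entry)
    assert out.length == c.length + (e - s)
    assert len(out.genes) == len(c.genes) + 2
    assert out.sequence[s:e] == out.sequence[e : e + (e - s)]


def test_deletion_removes_span(base_cluster):
    c = base_cluster
    s, e = c.genes[3].start, c.genes[4].end
    entry = EventLogEntry("indel", ("p", "q"), c.cluster_id, (s, e),
                          (e - s) / 1000.0, payload={"kind": "del"})
    out = apply_event(c, entry)
    assert out.length == c.length - (e - s)
    assert len(out.genes) == len(c.genes) - 2
    assert out.sequence == c.sequence[:s] + c.sequence[e:]


def test_gene_conversion_makes_domains_identical(rng):
    cfg = SimConfig(seed=3, homogeneous_types=())
    c = build_assembly_line(cfg, rng, "al", n_modules=4, pks=True)
    ks = [d for d in c.domains_in_order() if d.nrps_pks_type == "KS"]
    donor, acceptor = ks[0], ks[2]
    assert global_identity(donor.aa_seq, acceptor.aa_seq) < 100.0
    span = __import__("bgcevo.simulate", fromlist=["domain_nt_span"]) \
        .domain_nt_span(c, acceptor)
    entry = EventLogEntry("gene_conversion", ("p", "q"), c.cluster_id, span,
                          (span[1] - span[0]) / 1000.0,
                          payload={"donor_domain_id": donor.domain_id,
                                   "acceptor_domain_id": acceptor.domain_id})
    out = apply_event(c, entry)
    assert out.length == c.length
    d2 = {d.domain_id: d for d in out.domains}
    assert d2[donor.domain_id].aa_seq == d2[acceptor.domain_id].aa_seq


# ---------------------------------------------------------------------------
# assembly lines


def test_four_module_pks_has_twelve_typed_domains(rng):
    c = build_assembly_line(SimConfig(seed=0), rng, "pks4", n_modules=4,
                            pks=True)
    doms = c.domains_in_order()
    assert len(doms) == 12
    assert [d.nrps_pks_type for d in doms] == ["KS", "AT", "T"] * 4
    assert [d.module_index for d in doms] == sum(([m] * 3 for m in range(4)),
                                                 [])


def test_module_duplication_extends_line_with_identical_module(rng):
    c = build_assembly_line(SimConfig(seed=1), rng, "al", n_modules=4,
                            pks=False)
    g1 = c.genes[1]
    entry = EventLogEntry("module_duplication", ("p", "q"), c.cluster_id,
                          (g1.start, g1.end), g1.length / 1000.0,
                          payload={"suffix": "_m"})
    out = apply_event(c, entry)
    assert len(out.genes) == 5
    assert max(d.module_index for d in out.domains) == 4
    copies = [g for g in out.genes if g.gene_id.startswith(g1.gene_id)]
    assert copies[0].protein == copies[1].protein


def test_zero_modules_is_an_error(rng):
    with pytest.raises(ValueError, match="module"):
        build_assembly_line(SimConfig(seed=0), rng, "bad", n_modules=0)


def test_gene_conversion_raises_within_cluster_same_type_identity():
    concerted = SimConfig(seed=21, n_organisms=5, n_ancestral_clusters=1,
                          nrps_pks_fraction=1.0, substitution_rate=0.02,
                          gene_conversion_rate=2.0)
    vertical = SimConfig(seed=21, n_organisms=5, n_ancestral_clusters=1,
                         nrps_pks_fraction=1.0, substitution_rate=0.02,
                         homogeneous_types=())

    def mean_within(corpus):
        vals = []
        for c in corpus:
            by_type = {}
            for d in c.domains:
                by_type.setdefault(d.nrps_pks_type, []).append(d.aa_seq)
            for seqs in by_type.values():
                vals += [global_identity(a, b)
                         for a, b in itertools.combinations(seqs, 2)]
        return np.mean(vals)

    conc, _l, _n, _d = simulate_corpus(concerted)
    vert, _l2, _n2, _d2 = simulate_corpus(vertical)
    assert mean_within(conc) > mean_within(vert)
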