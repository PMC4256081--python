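"""Study-condition generators built on the simulator.

Each function here defines one simulated experiment used throughout the
test and acceptance suites: single-event cluster pairs for the block
caller, a profiling corpus with a co-transferred sub-cluster, assembly-line
corpora in four evolutionary modes, constructed corpora for the vertical
evolution index sign checks, and a planted sub-cluster sharing corpus.
The parameter values are the package's fixed study conditions, documented
in the methods note; they are not tuning knobs.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np

from .model import (
    Corpus,
    DomainAnnotation,
    Gene,
    GeneCluster,
    assign_order_index,
)
from .simulate import (
    DOMAIN_AA_LEN,
    EventLogEntry,
    SimConfig,
    apply_event,
    build_assembly_line,
    make_ancestral_cluster,
    simulate_corpus,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: per-branch, per-site substitution probability for single-event pairs;
#: two branches give pair identities around 92% (>= the 85% floor of the
#: block caller's working range)
EVENT_PAIR_SUB_RATE = 0.04


def _substitute(cluster: GeneCluster, rate: float, rng: np.random.Generator,
                branch=("anc", "tip")) -> GeneCluster:
    from .simulate import _draw_substitutions

    entry = _draw_substitutions(cluster, rate, rng, branch)
    return apply_event(cluster, entry) if entry is not None else cluster


def simulate_event_pair(
    event_type: str, seed: int, sub_rate: float = EVENT_PAIR_SUB_RATE
) -> tuple[GeneCluster, GeneCluster, EventLogEntry]:
    """One homologous cluster pair with exactly one planted event on the A
    branch (plus substitutions on both branches).

    ``event_type``: ``indel`` (gene-scale deletion >= 3 kb), ``duplication``
    (tandem two-gene copy) or ``inversion`` (two-to-three gene segment).
    """
    cfg = SimConfig(seed=seed, genes_per_cluster=(12, 15),
                    gene_length=(1000, 1500))
    rng = np.random.default_rng(seed)
    ancestor = make_ancestral_cluster(cfg, rng, "anc")
    a = ancestor.copy()
    a.cluster_id, a.organism_id = "A", "orgA"
    b = ancestor.copy()
    b.cluster_id, b.organism_id = "B", "orgB"
    a = _substitute(a, sub_rate, rng)
    b = _substitute(b, sub_rate, rng)

    genes = a.genes
    if event_type == "indel":
        n_del = 3
        i = int(rng.integers(3, len(genes) - n_del - 2))
        span = (genes[i].start, genes[i + n_del - 1].end)
        entry = EventLogEntry("indel", ("anc", "A"), "A", span,
                              (span[1] - span[0]) / 1000.0,
                              payload={"kind": "del"})
    elif event_type == "duplication":
        i = int(rng.integers(3, len(genes) - 4))
        span = (genes[i].start, genes[i + 1].end)
        entry = EventLogEntry("duplication", ("anc", "A"), "A", span,
                              (span[1] - span[0]) / 1000.0,
                              payload={"suffix": "_dup"})
    elif event_type == "inversion":
        n_inv = int(rng.integers(2, 4))
        i = int(rng.integers(3, len(genes) - n_inv - 2))
        span = (genes[i].start, genes[i + n_inv - 1].end)
        entry = EventLogEntry("inversion", ("anc", "A"), "A", span,
                              (span[1] - span[0]) / 1000.0)
    else:
        raise ValueError(f"unknown planted event type {event_type!r}")
    a = apply_event(a, entry)
    return a, b, entry


#: the block-caller call type each planted event surfaces as
EXPECTED_CALL_TYPE = {
    "indel": "indel",
    "duplication": "duplication",
    "inversion": "rearrangement",
}


# ---------------------------------------------------------------------------
# phylogenetic-profiling corpus with a co-transferred sub-cluster


def _mutate_aa(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    s = list(seq)
    if n_subs == 0:
        return seq
    for pos in rng.choice(len(s), size=min(n_subs, len(s)), replace=False):
        cands = [c for c in AA20 if c != s[pos]]
        s[pos] = cands[int(rng.integers(len(cands)))]
    return "".join(s)


def _protein_cluster(
    cluster_id: str, organism_id: str, domain_seqs: list[tuple[str, str]]
) -> GeneCluster:
    """A protein-space cluster (no nucleotide sequence): one gene per
    domain, stacked coordinates. ``domain_seqs`` = [(pfam_id, aa_seq)]."""
    genes, domains, pos = [], [], 0
    for i, (pfam, aa) in enumerate(domain_seqs):
        gid = f"{cluster_id}_g{i:02d}"
        nt_len = 3 * len(aa)
        genes.append(Gene(gid, pos, pos + nt_len, 1, aa))
        domains.append(DomainAnnotation(
            domain_id=f"{cluster_id}_d{i:02d}", pfam_id=pfam, gene_id=gid,
            order_index=0, aa_seq=aa, aa_start=0, aa_end=len(aa)))
        pos += nt_len
    return GeneCluster(cluster_id=cluster_id, organism_id=organism_id,
                       genes=genes,
                       domains=assign_order_index(genes, domains))


def simulate_profiling_corpus(
    seed: int, n_organisms: int = 20, clusters_per_organism: int = 2,
    n_background_pfams: int = 12, domains_per_cluster: int = 5,
    cassette_organism_fraction: float = 0.9,
) -> tuple[Corpus, list[str]]:
    """40 clusters over 20 organisms with one co-transferred 4-domain
    sub-cluster planted into a subset of organisms.

    The cassette's four domains share a per-organism divergence from a
    common source (they travelled together), so their identity profiles
    across organisms co-vary; background domains get independent
    per-organism, per-domain divergences. Returns (corpus, planted Pfam ids
    in cassette order).
    """
    rng = np.random.default_rng(seed)
    cassette_pfams = [f"PFCAS{k}" for k in range(1, 5)]
    cassette_src = [(p, "".join(AA20[int(rng.integers(20))]
                                for _ in range(DOMAIN_AA_LEN)))
                    for p in cassette_pfams]
    bg_pool = {
        f"PFBG{j:02d}": "".join(AA20[int(rng.integers(20))]
                                for _ in range(DOMAIN_AA_LEN))
        for j in range(n_background_pfams)
    }
    carriers = sorted(
        rng.choice(n_organisms,
                   size=int(round(cassette_organism_fraction * n_organisms)),
                   replace=False).tolist())
    corpus: Corpus = []
    for o in range(n_organisms):
        org = f"org{o + 1:03d}"
        # one shared cassette divergence per carrier organism
        cassette_subs = int(rng.integers(0, 16))
        for c in range(clusters_per_organism):
            cid = f"bgc{o + 1:03d}_{c}"
            doms: list[tuple[str, str]] = []
            if o in carriers and c == 0:
                for pfam, src in cassette_src:
                    doms.append((pfam, _mutate_aa(src, cassette_subs, rng)))
            pfams = sorted(bg_pool)
            picks = rng.choice(len(pfams), size=domains_per_cluster,
                               replace=False)
            for j in sorted(int(x) for x in picks):
                pfam = pfams[j]
                doms.append((pfam,
                             _mutate_aa(bg_pool[pfam],
                                        int(rng.integers(0, 26)), rng)))
            corpus.append(_protein_cluster(cid, org, doms))
    return corpus, cassette_pfams


# ---------------------------------------------------------------------------
# assembly-line mode corpora (concerted / vertical / N-terminal / mixed)

MODES = ("concerted", "vertical", "nterm", "mixed")


def mode_config(mode: str, seed: int, n_organisms: int = 15) -> SimConfig:
    base = dict(seed=seed, n_organisms=n_organisms, n_ancestral_clusters=1,
                nrps_pks_fraction=1.0, n_modules=(4, 5),
                substitution_rate=0.02)
    if mode == "concerted":
        # homogeneous duplication origin maintained by frequent conversion
        return SimConfig(**base, gene_conversion_rate=2.0)
    if mode == "vertical":
        # independently-derived modules, no internal recombination
        return SimConfig(**base, homogeneous_types=())
    if mode == "mixed":
        # AT/A lineage homogenized, KS/C vertical: conversion restricted
        return SimConfig(**base, homogeneous_types=("AT", "A", "T"),
                         gene_conversion_rate=1.0,
                         conversion_domain_types=("AT", "A", "T"))
    raise ValueError(f"mode {mode!r} has no tree-based config")


def _grow_nterm_cluster(seed: int, n_rounds: int = 3) -> GeneCluster:
    """A cluster grown by repeated duplication of its most N-terminal
    module, with substitutions between rounds: newest (N-terminal) modules
    are the most mutually similar."""
    cfg = SimConfig(seed=seed, homogeneous_types=())
    rng = np.random.default_rng(seed)
    cl = build_assembly_line(cfg, rng, cluster_id=f"nt{seed}",
                             n_modules=2, pks=bool(rng.random() < 0.5))
    for r in range(n_rounds):
        cl = _substitute(cl, 0.03, rng)
        first = min(cl.genes, key=lambda g: g.start)
        entry = EventLogEntry("module_duplication", ("anc", "tip"),
                              cl.cluster_id, (first.start, first.end),
                              first.length / 1000.0,
                              payload={"suffix": f"_r{r}"})
        cl = apply_event(cl, entry)
    return cl


def simulate_mode_corpus(
    seed: int, n_per_mode: int = 15
) -> tuple[Corpus, dict[str, str]]:
    """Four-mode assembly-line corpus; returns (corpus, cluster -> mode)."""
    corpus: Corpus = []
    labels: dict[str, str] = {}
    for m, mode in enumerate(MODES):
        if mode == "nterm":
            for k in range(n_per_mode):
                cl = _grow_nterm_cluster(seed * 1000 + m * 100 + k)
                cl.cluster_id = f"{mode}{k:02d}"
                cl.class_label = cl.class_label or "NRPS"
                labels[cl.cluster_id] = mode
                corpus.append(cl)
            continue
        cfg = mode_config(mode, seed * 1000 + m * 100, n_organisms=n_per_mode)
        tips, _log, _nwk, _dist = simulate_corpus(cfg)
        for k, cl in enumerate(tips[:n_per_mode]):
            cl = cl.copy()
            cl.cluster_id = f"{mode}{k:02d}"
            labels[cl.cluster_id] = mode
            corpus.append(cl)
    return corpus, labels


def simulate_isi_corpus(
    seed: int, n_concerted: int = 50, n_vertical: int = 50
) -> tuple[Corpus, dict[str, str]]:
    """Concerted vs vertical assembly lines for the internal-similarity
    separation experiment (independent clusters, one tree tip each)."""
    corpus: Corpus = []
    labels: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for k in range(n_concerted):
        s = int(rng.integers(2**31))
        cfg = SimConfig(seed=s, n_modules=(4, 5), substitution_rate=0.02)
        r = np.random.default_rng(s)
        cl = build_assembly_line(cfg, r, cluster_id=f"conc{k:02d}")
        cl = _substitute(cl, 0.02, r)
        labels[cl.cluster_id] = "concerted"
        corpus.append(cl)
    for k in range(n_vertical):
        s = int(rng.integers(2**31))
        cfg = SimConfig(seed=s, n_modules=(4, 5), homogeneous_types=())
        r = np.random.default_rng(s)
        cl = build_assembly_line(cfg, r, cluster_id=f"vert{k:02d}")
        cl = _substitute(cl, 0.02, r)
        labels[cl.cluster_id] = "vertical"
        corpus.append(cl)
    return corpus, labels


# ---------------------------------------------------------------------------
# constructed corpora for the vertical-evolution-index sign checks


def robust_mean_identity_similarity(a: GeneCluster, b: GeneCluster) -> float:
    """Cluster similarity for VEI sign analyses: mean same-Pfam cross
    identity with the single best pair dropped (one recruited domain must
    not make two otherwise-unrelated clusters look similar); continuous,
    so empirical similarity ranks are informative in small corpora."""
    from .align import global_identity

    vals = sorted(
        global_identity(da.aa_seq, db.aa_seq)
        for da in a.domains for db in b.domains
        if da.pfam_id == db.pfam_id
    )
    if len(vals) < 2:
        return 0.0
    return float(np.mean(vals[:-1]))


def vei_corpus(kind: str, seed: int) -> tuple[Corpus, list[str]]:
    """Corpora with known VEI sign; returns (corpus, focal cluster ids).

    ``positive``: a vertically coherent family — its member-specific Pfam
    families occur nowhere else (hit identities unexceptional within their
    own distribution) while family cluster pairs are exceptionally similar
    overall. ``negative``: a focal cluster has stolen one near-identical
    domain from a family it is otherwise unrelated to, so its hits are
    top-percentile identities in dissimilar clusters. ``null``:
    exchangeable clusters. Evaluate with
    :func:`robust_mean_identity_similarity` as the cluster-similarity
    function.
    """
    rng = np.random.default_rng(seed)

    def rand_aa(n=DOMAIN_AA_LEN):
        return "".join(AA20[int(rng.integers(20))] for _ in range(n))

    def conserved(src, n_subs):
        return _mutate_aa(src, n_subs, rng)

    corpus: Corpus = []
    if kind == "positive":
        # one vertically coherent family over a conserved-anchor background
        anchor_src = [(f"PFA{j}", rand_aa()) for j in range(3)]
        family_src = [(f"PFF{j}", rand_aa()) for j in range(2)]
        for k in range(8):
            doms = [(p, conserved(s, 7)) for p, s in anchor_src]
            doms += [(p, conserved(s, 3)) for p, s in family_src]
            corpus.append(_protein_cluster(f"fam{k}", f"orgF{k}", doms))
        for k in range(6):
            # background carries the broadly conserved anchors only
            doms = [(p, conserved(s, 9)) for p, s in anchor_src]
            doms += [(f"PFB{k}_{j}", rand_aa()) for j in range(2)]
            corpus.append(_protein_cluster(f"bg{k}", f"orgB{k}", doms))
        return corpus, [f"fam{k}" for k in range(8)]
    if kind == "negative":
        # four tight families with family-specific Pfams; the focal cluster
        # steals one near-identical domain from a member of each family
        stolen_doms = []
        for f in range(4):
            src = [(f"PFF{f}_{j}", rand_aa()) for j in range(3)]
            for k in range(3):
                doms = [(p, conserved(s, 5)) for p, s in src]
                corpus.append(
                    _protein_cluster(f"fam{f}_{k}", f"orgF{f}_{k}", doms))
            donor = corpus[-3]  # first member of family f
            d = donor.domains_in_order()[0]
            stolen_doms.append((d.pfam_id, _mutate_aa(d.aa_seq, 1, rng)))
        stolen_doms.append(("PFZ0", rand_aa()))
        corpus.append(_protein_cluster("focal", "orgZ", stolen_doms))
        return corpus, ["focal"]
    if kind == "null":
        pfams = [f"PFN{j}" for j in range(5)]
        for k in range(12):
            doms = [(p, rand_aa()) for p in pfams]
            corpus.append(_protein_cluster(f"ex{k:02d}", f"orgN{k}", doms))
        return corpus, [c.cluster_id for c in corpus]
    raise ValueError(f"unknown VEI corpus kind {kind!r}")


# ---------------------------------------------------------------------------
# coupled sequence / product-fingerprint divergence (similarity scatter)


def coupled_family_with_fingerprints(
    seed: int, n_clusters: int = 14, n_bits: int = 128
) -> tuple[Corpus, dict[str, "Fingerprint"]]:
    """A cluster family whose members diverge from a common source by
    varying amounts, with product fingerprints whose bit flips scale with
    the same divergence — sequence similarity (percentile Jaccard) and
    product similarity (Tanimoto) are positively coupled by construction.
    """
    from .model import Fingerprint

    rng = np.random.default_rng(seed)
    pfams = [f"PFC{j}" for j in range(5)]
    src = [(p, "".join(AA20[int(rng.integers(20))]
                       for _ in range(DOMAIN_AA_LEN))) for p in pfams]
    base_bits = rng.integers(0, 2, n_bits)
    corpus: Corpus = []
    fingerprints: dict[str, Fingerprint] = {}
    for k in range(n_clusters):
        divergence = k / (n_clusters - 1)  # 0 (identical) .. 1 (far)
        n_subs = int(round(divergence * DOMAIN_AA_LEN * 0.7))
        doms = [(p, _mutate_aa(s, n_subs, rng)) for p, s in src]
        cid = f"memb{k:02d}"
        corpus.append(_protein_cluster(cid, f"orgC{k}", doms))
        bits = base_bits.copy()
        n_flips = int(round(divergence * n_bits * 0.5))
        if n_flips:
            flip = rng.choice(n_bits, size=n_flips, replace=False)
            bits[flip] = 1 - bits[flip]
        fingerprints[cid] = Fingerprint(tuple(int(b) for b in bits), n_bits)
    return corpus, fingerprints


# ---------------------------------------------------------------------------
# planted sub-cluster sharing corpus


def planted_subcluster_corpus(
    seed: int, n_clusters: int = 8, n_carriers: int = 4
) -> tuple[Corpus, list[str], list[str]]:
    """Unrelated protein-space clusters, ``n_carriers`` of which carry a
    lightly diverged copy of a 3-gene sub-cluster cassette.

    Returns (corpus, carrier cluster ids, cassette gene ids in the first
    carrier).
    """
    rng = np.random.default_rng(seed)

    def rand_aa(n=120):
        return "".join(AA20[int(rng.integers(20))] for _ in range(n))

    cassette = [(f"PFSC{j}", rand_aa()) for j in range(3)]
    corpus: Corpus = []
    carriers = []
    for k in range(n_clusters):
        cid = f"cl{k:02d}"
        doms = [(f"PFU{k}_{j}", rand_aa()) for j in range(4)]
        if k < n_carriers:
            doms = [(p, _mutate_aa(s, 6, rng)) for p, s in cassette] + doms
            carriers.append(cid)
        corpus.append(_protein_cluster(cid, f"org{k:02d}", doms))
    first = corpus[0]
    cassette_genes = [first.genes[j].gene_id for j in range(3)]
    return corpus, carriers, cassette_genes


# ---------------------------------------------------------------------------
# HGT vs vertical corpora for best-hit organism distances


def hgt_and_vertical_corpora(seed: int, n_organisms: int = 14):
    """Two corpora on the same-sized trees: one evolving strictly
    vertically, one with frequent cross-lineage sub-cluster transfers.

    Enough organisms that a vertically inherited domain's nearest relative
    sits in a nearby tip, and substitutions fast enough that 50-aa domain
    windows rarely tie across organisms."""
    vert_cfg = SimConfig(seed=seed, n_organisms=n_organisms,
                         n_ancestral_clusters=2, substitution_rate=0.06)
    hgt_cfg = dc_replace(vert_cfg, transfer_rate=1.5, seed=seed + 1)
    vert = simulate_corpus(vert_cfg)
    hgt = simulate_corpus(hgt_cfg)
    return vert, hgt
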