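"""Synthetic BGC-evolution simulator with ground-truth event logs.

Corpora of gene clusters evolve along a pure-birth organism tree under
gene-scale operators — substitutions, segment indels, tandem duplications,
inversions, cross-lineage sub-cluster transfers, assembly-line module
duplications, and intra-cluster gene conversion. Every operation is recorded
as an :class:`EventLogEntry` carrying enough payload that replaying the log
from the ancestral clusters reproduces the tip clusters exactly; the log is
the recovery oracle for every downstream caller.

The qualitative model emulated: modular NRPS/PKS assembly lines whose
duplicated modules can be homogenized by recurrent gene conversion
(concerted evolution), clusters that grow by N-terminal module duplication,
sub-clusters that hop between clusters and lineages, and vertically
inherited clusters accumulating only substitutions and occasional indels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np
from Bio.Seq import Seq
from dendropy.simulate import treesim

from .align import reverse_complement
from .model import (
    Corpus,
    DomainAnnotation,
    Gene,
    GeneCluster,
    OrganismDistanceTable,
    assign_order_index,
)

EVENT_TYPES = (
    "substitution_batch",
    "indel",
    "duplication",
    "inversion",
    "transfer",
    "module_duplication",
    "gene_conversion",
)

DOMAIN_AA_LEN = 50
#: per-module domain layout within an assembly-line gene's protein
MODULE_AA_LEN = 180
MODULE_DOMAIN_WINDOWS = [(5, 55), (65, 115), (125, 175)]
NRPS_MODULE = [("PF_C", "C"), ("PF_A", "A"), ("PF_T1", "T")]
PKS_MODULE = [("PF_KS", "KS"), ("PF_AT", "AT"), ("PF_T2", "T")]


@dataclass
class SimConfig:
    """Study conditions for one simulated corpus.

    All event rates are Poisson means per branch; ``substitution_rate`` is a
    per-site, per-branch substitution probability. Branch lengths affect only
    the organism distance table.
    """

    seed: int = 0
    n_organisms: int = 12
    n_ancestral_clusters: int = 2
    genes_per_cluster: tuple[int, int] = (6, 10)
    gene_length: tuple[int, int] = (900, 1800)  # bp, rounded to codons
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    indel_size_kb: tuple[float, float] = (1.0, 6.0)
    indel_insert_prob: float = 0.5
    duplication_rate: float = 0.0
    inversion_rate: float = 0.0
    transfer_rate: float = 0.0
    module_duplication_rate: float = 0.0
    gene_conversion_rate: float = 0.0
    nrps_pks_fraction: float = 0.0
    n_modules: tuple[int, int] = (4, 6)
    pks_prob: float = 0.5
    #: domain types eligible for gene conversion (concerted evolution)
    conversion_domain_types: tuple[str, ...] = ("KS", "AT", "C", "A", "T")
    #: assembly-line domain types built as copies of module 0 at the root
    homogeneous_types: tuple[str, ...] = ("KS", "AT", "C", "A", "T")
    n_pfam_pool: int = 30

    def validate(self) -> None:
        rates = [
            self.substitution_rate, self.indel_rate, self.duplication_rate,
            self.inversion_rate, self.transfer_rate,
            self.module_duplication_rate, self.gene_conversion_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if self.indel_rate > 0 and self.indel_insert_prob == 0:
            n_branches = 2 * self.n_organisms - 2
            mean_del_bp = 500.0 * sum(self.indel_size_kb)
            min_len = self.genes_per_cluster[0] * self.gene_length[0]
            if self.indel_rate * n_branches * mean_del_bp >= min_len:
                raise ValueError(
                    "deletion-only indel rate implies expected cluster "
                    "length <= 0"
                )


@dataclass
class EventLogEntry:
    """One ground-truth evolutionary operation.

    ``payload`` carries whatever the operation needs to be replayed exactly
    (substitution lists, inserted fragments, new ids) and is opaque to
    downstream consumers.
    """

    event_type: str
    branch: tuple[str, str]
    cluster_id: str
    span: tuple[int, int]
    size_kb: float
    donor: Optional[tuple[str, tuple[int, int]]] = None
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def _rederive(cluster: GeneCluster) -> GeneCluster:
    """Recompute proteins and domain aa sequences from the nucleotide
    sequence, and reassign domain order / assembly-line module indices."""
    seq = cluster.sequence
    assert seq is not None
    new_genes = []
    prot_by_gene: dict[str, str] = {}
    for g in sorted(cluster.genes, key=lambda g: g.start):
        nt = seq[g.start : g.end]
        if g.strand == -1:
            nt = reverse_complement(nt)
        prot = translate(nt)
        prot_by_gene[g.gene_id] = prot
        new_genes.append(Gene(g.gene_id, g.start, g.end, g.strand, prot))
    new_domains = []
    for d in cluster.domains:
        prot = prot_by_gene[d.gene_id]
        aa = prot[d.aa_start : d.aa_end] if d.aa_start is not None else prot
        new_domains.append(replace(d, aa_seq=aa))
    new_domains = assign_order_index(new_genes, new_domains)
    # module_index follows gene order for typed (assembly-line) domains
    module_genes = []
    for g in new_genes:
        if any(d.gene_id == g.gene_id and d.nrps_pks_type for d in new_domains):
            module_genes.append(g.gene_id)
    mod_rank = {gid: i for i, gid in enumerate(module_genes)}
    new_domains = [
        replace(d, module_index=mod_rank[d.gene_id])
        if d.nrps_pks_type is not None and d.gene_id in mod_rank
        else d
        for d in new_domains
    ]
    out = cluster.copy()
    out.genes = new_genes
    out.domains = new_domains
    out.validate()
    return out


def domain_nt_span(cluster: GeneCluster, domain: DomainAnnotation) -> tuple[int, int]:
    g = cluster.gene(domain.gene_id)
    assert domain.aa_start is not None and domain.aa_end is not None
    if g.strand == 1:
        return g.start + 3 * domain.aa_start, g.start + 3 * domain.aa_end
    return g.end - 3 * domain.aa_end, g.end - 3 * domain.aa_start


# ---------------------------------------------------------------------------
# structural operators (coordinate remapping)


def _shift_genes(genes: list[Gene], at: int, delta: int) -> list[Gene]:
    return [
        Gene(g.gene_id, g.start + delta, g.end + delta, g.strand, g.protein)
        if g.start >= at
        else g
        for g in genes
    ]


def _delete_span(cluster: GeneCluster, s: int, e: int) -> GeneCluster:
    out = cluster.copy()
    out.sequence = cluster.sequence[:s] + cluster.sequence[e:]
    kept = [g for g in cluster.genes if g.end <= s or g.start >= e]
    kept_ids = {g.gene_id for g in kept}
    out.genes = _shift_genes(kept, e, s - e)
    out.domains = [d for d in cluster.domains if d.gene_id in kept_ids]
    return out


def _insert_fragment(
    cluster: GeneCluster, pos: int, frag_seq: str,
    frag_genes: list[Gene], frag_domains: list[DomainAnnotation],
) -> GeneCluster:
    out = cluster.copy()
    out.sequence = cluster.sequence[:pos] + frag_seq + cluster.sequence[pos:]
    shifted = _shift_genes(list(cluster.genes), pos, len(frag_seq))
    placed = [
        Gene(g.gene_id, g.start + pos, g.end + pos, g.strand, g.protein)
        for g in frag_genes
    ]
    out.genes = sorted(shifted + placed, key=lambda g: g.start)
    out.domains = list(cluster.domains) + list(frag_domains)
    return out


def _invert_span(cluster: GeneCluster, s: int, e: int) -> GeneCluster:
    out = cluster.copy()
    out.sequence = (
        cluster.sequence[:s]
        + reverse_complement(cluster.sequence[s:e])
        + cluster.sequence[e:]
    )
    new_genes = []
    for g in cluster.genes:
        if g.start >= s and g.end <= e:
            new_genes.append(
                Gene(g.gene_id, s + e - g.end, s + e - g.start, -g.strand,
                     g.protein)
            )
        else:
            new_genes.append(g)
    out.genes = sorted(new_genes, key=lambda g: g.start)
    out.domains = list(cluster.domains)
    return out


def _copy_gene_run(
    cluster: GeneCluster, s: int, e: int, suffix: str
) -> tuple[str, list[Gene], list[DomainAnnotation]]:
    """Extract a gene-aligned span as a relocatable fragment with fresh ids."""
    frag_seq = cluster.sequence[s:e]
    frag_genes, frag_domains = [], []
    for g in cluster.genes:
        if g.start >= s and g.end <= e:
            new_id = f"{g.gene_id}{suffix}"
            frag_genes.append(
                Gene(new_id, g.start - s, g.end - s, g.strand, g.protein)
            )
            for d in cluster.domains:
                if d.gene_id == g.gene_id:
                    frag_domains.append(
                        replace(d, domain_id=f"{d.domain_id}{suffix}",
                                gene_id=new_id)
                    )
    return frag_seq, frag_genes, frag_domains


# ---------------------------------------------------------------------------
# event application


def apply_event(
    cluster: GeneCluster, entry: EventLogEntry, rng=None
) -> GeneCluster:
    """Apply one fully-specified event; deterministic, ``rng`` unused.

    Coordinates in ``entry.span`` refer to the cluster as passed in.
    """
    et = entry.event_type
    s, e = entry.span
    inserting = (et == "transfer"
                 or (et == "indel" and entry.payload.get("kind") == "ins"))
    if inserting:
        if not (0 <= s <= cluster.length):
            raise ValueError(f"insertion point {s} outside cluster of length "
                             f"{cluster.length}")
    elif et != "substitution_batch" and not (0 <= s <= e <= cluster.length):
        raise ValueError(f"span {entry.span} outside cluster of length "
                         f"{cluster.length}")
    if et == "substitution_batch":
        seq = list(cluster.sequence)
        for pos, base in entry.payload["subs"]:
            seq[pos] = base
        out = cluster.copy()
        out.sequence = "".join(seq)
    elif et == "indel":
        if entry.payload["kind"] == "del":
            out = _delete_span(cluster, s, e)
        else:
            frag = entry.payload["fragment"]
            out = _insert_fragment(cluster, s, frag["sequence"],
                                   frag["genes"], frag["domains"])
    elif et in ("duplication", "module_duplication"):
        frag_seq, frag_genes, frag_domains = _copy_gene_run(
            cluster, s, e, entry.payload["suffix"]
        )
        if not frag_genes:
            raise ValueError("duplication span crosses no gene boundary")
        out = _insert_fragment(cluster, e, frag_seq, frag_genes, frag_domains)
    elif et == "inversion":
        if not any(g.start >= s and g.end <= e for g in cluster.genes):
            raise ValueError("inversion span crosses no gene boundary")
        out = _invert_span(cluster, s, e)
    elif et == "transfer":
        frag = entry.payload["fragment"]
        out = _insert_fragment(cluster, s, frag["sequence"], frag["genes"],
                               frag["domains"])
    elif et == "gene_conversion":
        donor_d = next(d for d in cluster.domains
                       if d.domain_id == entry.payload["donor_domain_id"])
        acc_d = next(d for d in cluster.domains
                     if d.domain_id == entry.payload["acceptor_domain_id"])
        ds, de = domain_nt_span(cluster, donor_d)
        as_, ae = domain_nt_span(cluster, acc_d)
        if de - ds != ae - as_:
            raise ValueError("gene conversion requires equal-length domains")
        donor_nt = cluster.sequence[ds:de]
        if cluster.gene(donor_d.gene_id).strand == -1:
            donor_nt = reverse_complement(donor_nt)
        if cluster.gene(acc_d.gene_id).strand == -1:
            donor_nt = reverse_complement(donor_nt)
        out = cluster.copy()
        out.sequence = (cluster.sequence[:as_] + donor_nt
                        + cluster.sequence[ae:])
    else:  # pragma: no cover
        raise ValueError(et)
    return _rederive(out)


# ---------------------------------------------------------------------------
# ancestral cluster construction


def _make_gene(
    rng: np.random.Generator, gene_id: str, start: int, length: int,
    pfam_id: str, domain_id: str,
) -> tuple[Gene, DomainAnnotation]:
    length -= length % 3
    nt = random_dna(rng, length)
    prot = translate(nt)
    gene = Gene(gene_id, start, start + length, 1, prot)
    dom = DomainAnnotation(
        domain_id=domain_id, pfam_id=pfam_id, gene_id=gene_id, order_index=0,
        aa_seq=prot[5 : 5 + DOMAIN_AA_LEN], aa_start=5,
        aa_end=5 + DOMAIN_AA_LEN,
    )
    return gene, dom


def make_ancestral_cluster(
    config: SimConfig, rng: np.random.Generator, cluster_id: str,
    organism_id: str = "ancestor", pfam_ids: Optional[list[str]] = None,
) -> GeneCluster:
    """A cluster of ordinary (non-assembly-line) genes, one Pfam domain per
    gene, drawn from the configured Pfam pool unless ``pfam_ids`` is given."""
    n_genes = int(rng.integers(config.genes_per_cluster[0],
                               config.genes_per_cluster[1] + 1))
    if pfam_ids is None:
        pool = [f"PF{i:05d}" for i in range(1, config.n_pfam_pool + 1)]
        pfam_ids = [pool[int(rng.integers(len(pool)))] for _ in range(n_genes)]
    genes, domains, seq_parts, pos = [], [], [], 0
    for i, pfam in enumerate(pfam_ids):
        length = int(rng.integers(config.gene_length[0],
                                  config.gene_length[1] + 1))
        length -= length % 3
        g, d = _make_gene(rng, f"{cluster_id}_g{i:02d}", pos, length, pfam,
                          f"{cluster_id}_d{i:02d}")
        genes.append(g)
        domains.append(d)
        pos = g.end
    seq = ""
    rng2 = np.random.default_rng(int(rng.integers(2**31)))
    # regenerate contiguous sequence consistent with gene proteins
    seq_parts = []
    for g in genes:
        nt = random_dna(rng2, g.length)
        seq_parts.append(nt)
    seq = "".join(seq_parts)
    cluster = GeneCluster(cluster_id=cluster_id, organism_id=organism_id,
                          genes=genes, domains=assign_order_index(genes, domains),
                          sequence=seq)
    return _rederive(cluster)


def build_assembly_line(
    config: SimConfig, rng: np.random.Generator, cluster_id: str = "al0",
    organism_id: str = "ancestor", n_modules: Optional[int] = None,
    pks: Optional[bool] = None,
) -> GeneCluster:
    """A multimodular NRPS/PKS cluster: one gene per module, each carrying a
    C-A-T or KS-AT-T domain triplet. Domain types in
    ``config.homogeneous_types`` are built as exact copies of module 0's
    domain (a duplication origin); the rest are drawn independently."""
    if n_modules is None:
        n_modules = int(rng.integers(config.n_modules[0],
                                     config.n_modules[1] + 1))
    if n_modules < 1:
        raise ValueError("assembly line needs at least 1 module")
    if pks is None:
        pks = bool(rng.random() < config.pks_prob)
    layout = PKS_MODULE if pks else NRPS_MODULE
    gene_nt_len = MODULE_AA_LEN * 3
    module_seqs: list[str] = []
    for m in range(n_modules):
        nt = random_dna(rng, gene_nt_len)
        if m > 0:
            for (aa_s, aa_e), (_pfam, dtype) in zip(MODULE_DOMAIN_WINDOWS,
                                                    layout):
                if dtype in config.homogeneous_types:
                    nt = (nt[: 3 * aa_s] + module_seqs[0][3 * aa_s : 3 * aa_e]
                          + nt[3 * aa_e :])
        module_seqs.append(nt)
    genes, domains = [], []
    for m, nt in enumerate(module_seqs):
        gid = f"{cluster_id}_m{m:02d}"
        prot = translate(nt)
        genes.append(Gene(gid, m * gene_nt_len, (m + 1) * gene_nt_len, 1, prot))
        for k, ((aa_s, aa_e), (pfam, dtype)) in enumerate(
            zip(MODULE_DOMAIN_WINDOWS, layout)
        ):
            domains.append(
                DomainAnnotation(
                    domain_id=f"{gid}_{dtype}", pfam_id=pfam, gene_id=gid,
                    order_index=0, aa_seq=prot[aa_s:aa_e],
                    nrps_pks_type=dtype, module_index=m,
                    aa_start=aa_s, aa_end=aa_e,
                )
            )
    cluster = GeneCluster(
        cluster_id=cluster_id, organism_id=organism_id, genes=genes,
        domains=assign_order_index(genes, domains),
        sequence="".join(module_seqs),
        class_label="PKS" if pks else "NRPS",
    )
    return _rederive(cluster)


# ---------------------------------------------------------------------------
# per-branch evolution


def _draw_substitutions(
    cluster: GeneCluster, rate: float, rng: np.random.Generator,
    branch: tuple[str, str],
) -> Optional[EventLogEntry]:
    L = cluster.length
    n = int(rng.binomial(L, min(rate, 1.0))) if rate > 0 else 0
    if n == 0:
        return None
    positions = rng.choice(L, size=n, replace=False)
    subs = []
    for pos in sorted(int(p) for p in positions):
        old = cluster.sequence[pos]
        choices = [b for b in "ACGT" if b != old]
        subs.append((pos, choices[int(rng.integers(3))]))
    return EventLogEntry("substitution_batch", branch, cluster.cluster_id,
                         (0, L), n / 1000.0, payload={"subs": subs})


def _gene_run_span(
    cluster: GeneCluster, rng: np.random.Generator, n_genes: int,
    margin: int = 0,
) -> Optional[tuple[int, int]]:
    genes = cluster.genes
    if len(genes) < n_genes + 2 * margin:
        return None
    lo, hi = margin, len(genes) - n_genes - margin
    if hi < lo:
        return None
    i = int(rng.integers(lo, hi + 1))
    return genes[i].start, genes[i + n_genes - 1].end


def _fragment_payload(
    config: SimConfig, rng: np.random.Generator, prefix: str, target_bp: float
) -> dict:
    genes, domains, pos, i = [], [], 0, 0
    pool = [f"PF{i:05d}" for i in range(1, config.n_pfam_pool + 1)]
    while pos < target_bp:
        length = int(rng.integers(config.gene_length[0],
                                  config.gene_length[1] + 1))
        length -= length % 3
        g, d = _make_gene(rng, f"{prefix}_g{i}", pos, length,
                          pool[int(rng.integers(len(pool)))], f"{prefix}_d{i}")
        genes.append(g)
        domains.append(d)
        pos = g.end
        i += 1
    seq = "".join(random_dna(rng, g.length) for g in genes)
    frag = {"sequence": seq, "genes": genes, "domains": domains}
    # make fragment self-consistent (proteins from its own sequence)
    tmp = GeneCluster("frag", "frag", genes=genes,
                      domains=assign_order_index(genes, domains), sequence=seq)
    tmp = _rederive(tmp)
    return {"sequence": tmp.sequence, "genes": tmp.genes,
            "domains": tmp.domains}


def draw_branch_events(
    cluster: GeneCluster, config: SimConfig, rng: np.random.Generator,
    branch: tuple[str, str], donor_pool: list[GeneCluster],
    tag: str,
) -> list[EventLogEntry]:
    """Draw the Poisson event set for one branch; spans refer to the cluster
    state at the moment each event would apply (events are applied in the
    returned order)."""
    entries: list[EventLogEntry] = []
    state = cluster
    sub = _draw_substitutions(state, config.substitution_rate, rng, branch)
    if sub is not None:
        entries.append(sub)
        state = apply_event(state, sub)
    counters = {"indel": 0, "dup": 0, "inv": 0, "tra": 0, "mod": 0, "con": 0}

    def _apply(entry: EventLogEntry) -> None:
        nonlocal state
        entries.append(entry)
        state = apply_event(state, entry)

    for _ in range(rng.poisson(config.indel_rate)):
        counters["indel"] += 1
        want_ins = bool(rng.random() < config.indel_insert_prob)
        size_kb = float(rng.uniform(*config.indel_size_kb))
        if not want_ins:
            n_del = max(1, round(size_kb * 1000 / np.mean(config.gene_length)))
            span = _gene_run_span(state, rng, n_del, margin=2)
            if span is not None:
                _apply(EventLogEntry(
                    "indel", branch, state.cluster_id, span,
                    (span[1] - span[0]) / 1000.0, payload={"kind": "del"}))
                continue
        frag = _fragment_payload(
            config, rng, f"{state.cluster_id}_{tag}i{counters['indel']}",
            size_kb * 1000)
        boundaries = [g.start for g in state.genes[2:-1]] or [state.length]
        pos = boundaries[int(rng.integers(len(boundaries)))]
        _apply(EventLogEntry(
            "indel", branch, state.cluster_id,
            (pos, pos + len(frag["sequence"])),
            len(frag["sequence"]) / 1000.0,
            payload={"kind": "ins", "fragment": frag}))
    for _ in range(rng.poisson(config.duplication_rate)):
        counters["dup"] += 1
        n = int(rng.integers(1, 3))
        span = _gene_run_span(state, rng, n, margin=1)
        if span is None:
            continue
        _apply(EventLogEntry(
            "duplication", branch, state.cluster_id, span,
            (span[1] - span[0]) / 1000.0,
            payload={"suffix": f"_{tag}D{counters['dup']}"}))
    for _ in range(rng.poisson(config.inversion_rate)):
        counters["inv"] += 1
        n = int(rng.integers(2, 4))
        span = _gene_run_span(state, rng, n, margin=1)
        if span is None:
            continue
        _apply(EventLogEntry("inversion", branch, state.cluster_id, span,
                             (span[1] - span[0]) / 1000.0))
    for _ in range(rng.poisson(config.transfer_rate)):
        counters["tra"] += 1
        donors = [d for d in donor_pool if d.cluster_id != state.cluster_id
                  and len(d.genes) >= 2]
        if not donors:
            continue
        donor = donors[int(rng.integers(len(donors)))]
        n = int(rng.integers(2, min(4, len(donor.genes)) + 1))
        dspan = _gene_run_span(donor, rng, n)
        if dspan is None:
            continue
        frag_seq, frag_genes, frag_domains = _copy_gene_run(
            donor, dspan[0], dspan[1], f"_{tag}T{counters['tra']}")
        boundaries = [g.start for g in state.genes[1:]] or [state.length]
        pos = boundaries[int(rng.integers(len(boundaries)))]
        _apply(EventLogEntry(
            "transfer", branch, state.cluster_id,
            (pos, pos + len(frag_seq)), len(frag_seq) / 1000.0,
            donor=(donor.cluster_id, dspan),
            payload={"fragment": {"sequence": frag_seq, "genes": frag_genes,
                                  "domains": frag_domains}}))
    for _ in range(rng.poisson(config.module_duplication_rate)):
        counters["mod"] += 1
        mod_genes = sorted(
            {d.gene_id for d in state.domains if d.nrps_pks_type},
            key=lambda gid: state.gene(gid).start)
        if not mod_genes:
            continue
        g = state.gene(mod_genes[int(rng.integers(len(mod_genes)))])
        _apply(EventLogEntry(
            "module_duplication", branch, state.cluster_id,
            (g.start, g.end), g.length / 1000.0,
            payload={"suffix": f"_{tag}M{counters['mod']}"}))
    for _ in range(rng.poisson(config.gene_conversion_rate)):
        counters["con"] += 1
        by_type: dict[str, list[DomainAnnotation]] = {}
        for d in state.domains:
            if d.nrps_pks_type in config.conversion_domain_types:
                by_type.setdefault(d.nrps_pks_type, []).append(d)
        eligible = sorted(t for t, ds in by_type.items() if len(ds) >= 2)
        if not eligible:
            continue
        dtype = eligible[int(rng.integers(len(eligible)))]
        ds = sorted(by_type[dtype], key=lambda d: d.order_index)
        i, j = rng.choice(len(ds), size=2, replace=False)
        donor_d, acc_d = ds[int(i)], ds[int(j)]
        span = domain_nt_span(state, acc_d)
        _apply(EventLogEntry(
            "gene_conversion", branch, state.cluster_id, span,
            (span[1] - span[0]) / 1000.0,
            payload={"donor_domain_id": donor_d.domain_id,
                     "acceptor_domain_id": acc_d.domain_id}))
    return entries


# ---------------------------------------------------------------------------
# tree + corpus simulation


def simulate_tree(
    n_organisms: int, seed: int
) -> tuple[dendropy.Tree, list[str]]:
    """Pure-birth tree with exponential branch lengths; tips org001.. ."""
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_organisms, rng=rng)
    tips = []
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"org{i:03d}"
        tips.append(leaf.taxon.label)
    for i, node in enumerate(tree.preorder_node_iter()):
        node.sim_label = (node.taxon.label if node.taxon is not None
                          else f"node{i:03d}")
    return tree, tips


def tree_distance_table(tree: dendropy.Tree) -> OrganismDistanceTable:
    """Tip-to-tip path lengths normalized to [0, 1]."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    if d.max() > 0:
        d /= d.max()
    return OrganismDistanceTable([t.label for t in taxa], d)


def ancestral_clusters(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, GeneCluster]:
    """The root cluster per family, reconstructible from the config alone
    (the same draws `simulate_corpus` makes before walking the tree)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ancestors: dict[str, GeneCluster] = {}
    for f in range(config.n_ancestral_clusters):
        fam = f"fam{f:02d}"
        if rng.random() < config.nrps_pks_fraction:
            ancestors[fam] = build_assembly_line(config, rng, cluster_id=fam)
        else:
            ancestors[fam] = make_ancestral_cluster(config, rng, fam)
    return ancestors


def simulate_corpus(
    config: SimConfig,
) -> tuple[Corpus, list[EventLogEntry], str, OrganismDistanceTable]:
    """Evolve ``n_ancestral_clusters`` cluster families along one organism
    tree; returns (tip corpus, event log, newick tree, distance table)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree, _tips = simulate_tree(config.n_organisms, config.seed)
    ancestors = ancestral_clusters(config, rng)
    log: list[EventLogEntry] = []
    corpus: Corpus = []
    # preorder traversal; each node carries the per-family cluster states
    states: dict[int, dict[str, GeneCluster]] = {}
    visited_states: list[GeneCluster] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = dict(ancestors)
            continue
        parent_state = states[id(node.parent_node)]
        branch = (node.parent_node.sim_label, node.sim_label)
        child_state: dict[str, GeneCluster] = {}
        for fam in sorted(parent_state):
            cl = parent_state[fam].copy()
            cl.cluster_id = f"{fam}_{node.sim_label}"
            cl.organism_id = node.sim_label
            cl = _rederive(cl)
            donor_pool = sorted(
                [c for c in visited_states] + [
                    parent_state[f2] for f2 in sorted(parent_state)
                    if f2 != fam],
                key=lambda c: c.cluster_id)
            tag = f"{node.sim_label}"
            for entry in draw_branch_events(cl, config, rng, branch,
                                            donor_pool, tag):
                cl = apply_event(cl, entry)
                log.append(entry)
            child_state[fam] = cl
            visited_states.append(cl)
        states[id(node)] = child_state
        if node.is_leaf():
            corpus.extend(child_state[f] for f in sorted(child_state))
    corpus.sort(key=lambda c: c.cluster_id)
    newick = tree.as_string(schema="newick").strip()
    return corpus, log, newick, tree_distance_table(tree)


def replay_log(
    ancestors: dict[str, GeneCluster], log: list[EventLogEntry], newick: str
) -> Corpus:
    """Re-apply a recorded event log along the tree; must reproduce the tip
    corpus of the generating run exactly."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    by_branch: dict[tuple[str, str], list[EventLogEntry]] = {}
    for e in log:
        by_branch.setdefault(e.branch, []).append(e)
    # rebuild sim labels: tips keep taxon labels; internal nodes numbered in
    # preorder exactly as in simulate_corpus
    for i, node in enumerate(tree.preorder_node_iter()):
        node.sim_label = (node.taxon.label if node.taxon is not None
                          else f"node{i:03d}")
    states: dict[int, dict[str, GeneCluster]] = {}
    corpus: Corpus = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = dict(ancestors)
            continue
        branch = (node.parent_node.sim_label, node.sim_label)
        child_state = {}
        for fam in sorted(states[id(node.parent_node)]):
            cl = states[id(node.parent_node)][fam].copy()
            cl.cluster_id = f"{fam}_{node.sim_label}"
            cl.organism_id = node.sim_label
            cl = _rederive(cl)
            for entry in by_branch.get(branch, []):
                if entry.cluster_id == cl.cluster_id:
                    cl = apply_event(cl, entry)
            child_state[fam] = cl
        states[id(node)] = child_state
        if node.is_leaf():
            corpus.extend(child_state[f] for f in sorted(child_state))
    corpus.sort(key=lambda c: c.cluster_id)
    return corpus
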