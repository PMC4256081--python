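"""Cluster-level similarity indices and primary-metabolism comparisons.

The sequence-similarity index between two clusters is a Jaccard index over
Pfam domain pairs: a pair counts toward the intersection only when its
identity clears the top-10th-percentile of the corpus-wide identity
distribution for that Pfam family, so families with different evolutionary
rates are judged against their own backgrounds. Product structural
similarity is the Tanimoto coefficient on fingerprint bit vectors. The
horizontal-transfer proxy compares each domain's best cross-organism
homolog against an organism marker-distance table. Operon calling and
MCL-based organism dereplication support the primary-metabolism contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .align import global_identity
from .model import Corpus, Fingerprint, GeneCluster, OrganismDistanceTable

#: Pfam families of the histidine biosynthesis pathway
HIS_PFAMS = frozenset({"PF00475", "PF00815", "PF01174", "PF01502", "PF01634",
                       "PF04864", "PF08029", "PF08645"})
#: Pfam families of the tryptophan biosynthesis pathway
TRP_PFAMS = frozenset({"PF00218", "PF00290", "PF00465", "PF00697", "PF01220",
                       "PF01264", "PF01487", "PF04715", "PF08501"})

TOP_PERCENTILE = 90.0
MIN_PAIRS_PER_PFAM = 20


@dataclass
class SimilarityIndex:
    pair: tuple[str, str]
    jaccard: float
    n_top_pairs: int
    mean_top_identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError("jaccard outside [0, 1]")


class IdentityBackground:
    """Per-Pfam-ID distributions of cross-cluster same-family domain
    identities, with a pooled fallback for sparse families."""

    def __init__(self, per_pfam: dict[str, np.ndarray], pooled: np.ndarray,
                 excluded: list[str]):
        self.per_pfam = per_pfam
        self.pooled = pooled
        self.excluded = excluded

    def threshold(self, pfam_id: str, q: float = TOP_PERCENTILE) -> float:
        """Identity floor for the 'top (100-q)%' of the family's pairs."""
        dist = self.per_pfam.get(pfam_id)
        if dist is None or len(dist) < MIN_PAIRS_PER_PFAM:
            dist = self.pooled
        if len(dist) == 0:
            return 100.0
        return float(np.percentile(dist, q))

    def upper_tail_p(self, pfam_id: str, identity: float) -> float:
        """Empirical upper-tail p of an identity, (r+1)/(N+1) estimator."""
        dist = self.per_pfam.get(pfam_id)
        if dist is None or len(dist) < MIN_PAIRS_PER_PFAM:
            dist = self.pooled
        r = int(np.sum(dist >= identity))
        return (r + 1) / (len(dist) + 1)


def domain_identity_background(corpus: Corpus) -> IdentityBackground:
    """All cross-cluster same-Pfam-ID pair identities, sorted per family."""
    by_pfam: dict[str, list[tuple[str, str]]] = {}
    for c in corpus:
        for d in c.domains:
            by_pfam.setdefault(d.pfam_id, []).append((c.cluster_id, d.aa_seq))
    per_pfam: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    pooled: list[float] = []
    for pfam in sorted(by_pfam):
        members = by_pfam[pfam]
        vals = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i][0] == members[j][0]:
                    continue  # within-cluster pairs are not background
                vals.append(global_identity(members[i][1], members[j][1]))
        if not vals:
            excluded.append(pfam)
            continue
        per_pfam[pfam] = np.sort(np.asarray(vals))
        pooled.extend(vals)
    return IdentityBackground(per_pfam, np.sort(np.asarray(pooled)), excluded)


def bgc_jaccard(
    a: GeneCluster, b: GeneCluster, background: IdentityBackground
) -> SimilarityIndex:
    """Jaccard index over Pfam domain pairs above the per-family top-decile
    identity threshold, with greedy one-to-one matching.

    jaccard = |intersection| / (n_a + n_b − |intersection|) over domain
    instances.
    """
    n_a, n_b = len(a.domains), len(b.domains)
    pair_key = (a.cluster_id, b.cluster_id)
    cands: list[tuple[float, str, str, str]] = []
    for da in a.domains_in_order():
        for db in b.domains_in_order():
            if da.pfam_id != db.pfam_id:
                continue
            ident = global_identity(da.aa_seq, db.aa_seq)
            cands.append((ident, da.domain_id, db.domain_id, da.pfam_id))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matched: list[tuple[float, str]] = []
    for ident, ida, idb, pfam in cands:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        # boundary inclusive: a pair at exactly the 90th percentile is in
        # the top decile (keeps jaccard(a, a) = 1 in degenerate backgrounds)
        if ident >= background.threshold(pfam):
            matched.append((ident, pfam))
    k = len(matched)
    denom = n_a + n_b - k
    jac = k / denom if denom > 0 else 0.0
    mean_top = float(np.mean([m[0] for m in matched])) if matched else 0.0
    return SimilarityIndex(pair_key, jac, k, mean_top)


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """|a ∧ b| / |a ∨ b| on equal-length bit vectors."""
    if fa.n_bits != fb.n_bits:
        raise ValueError("fingerprints have different n_bits")
    av, bv = np.asarray(fa.bits, bool), np.asarray(fb.bits, bool)
    union = int(np.sum(av | bv))
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return float(np.sum(av & bv)) / union


def besthit_organism_distances(
    corpus: Corpus,
    distances: OrganismDistanceTable,
    scope: str = "bgc",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per domain: marker distance between its organism and the organism of
    its best cross-organism same-Pfam homolog.

    Returns (best-hit distances, background all-organism-pair distances,
    number of domains skipped for lack of a cross-organism homolog).
    ``scope`` is a label only; the caller selects which clusters to pass.
    """
    for c in corpus:
        if c.organism_id not in distances.organism_ids:
            raise KeyError(f"organism {c.organism_id!r} missing from table")
    all_domains = [
        (c.organism_id, d.pfam_id, d.aa_seq)
        for c in corpus
        for d in c.domains_in_order()
    ]
    out: list[float] = []
    skipped = 0
    for org, pfam, seq in all_domains:
        best: Optional[tuple[float, str]] = None
        for org2, pfam2, seq2 in all_domains:
            if org2 == org or pfam2 != pfam:
                continue
            ident = global_identity(seq, seq2)
            cand = (-ident, org2)  # ties: lexicographically first organism
            if best is None or cand < best:
                best = cand
        if best is None:
            skipped += 1
            continue
        out.append(distances.distance(org, best[1]))  # best = (-ident, org)
    n = len(distances.organism_ids)
    background = distances.distances[np.triu_indices(n, k=1)]
    return np.asarray(out), np.asarray(background), skipped


@dataclass
class OperonCall:
    organism_id: str
    gene_ids: tuple[str, ...]
    matched_pfams: tuple[str, ...]
    max_probability: float

    def __post_init__(self) -> None:
        if len(self.matched_pfams) < 2:
            raise ValueError("operon call needs >= 2 pathway domains")
        if self.max_probability <= 0.5:
            raise ValueError("operon call needs a probability > 0.5")


def find_operons(
    domain_table: list[tuple[str, str, str, float]],
    pathway_pfams: frozenset,
) -> list[OperonCall]:
    """Call pathway operons from per-gene domain rows
    ``(organism_id, gene_id, pfam_id, probability)`` in genomic order.

    A call is a contiguous run of pathway-domain genes (gaps of at most one
    intervening gene) containing >= 2 pathway domains, at least one with
    probability > 0.5.
    """
    calls: list[OperonCall] = []
    by_org: dict[str, list[tuple[str, str, float]]] = {}
    for org, gene, pfam, prob in domain_table:
        if not (0.0 <= prob <= 1.0):
            raise ValueError(f"probability {prob} outside [0, 1]")
        by_org.setdefault(org, []).append((gene, pfam, prob))
    for org in sorted(by_org):
        rows = by_org[org]
        gene_order: list[str] = []
        for gene, _pf, _pr in rows:
            if gene not in gene_order:
                gene_order.append(gene)
        gene_idx = {g: i for i, g in enumerate(gene_order)}
        pathway_rows = [(gene_idx[g], g, pf, pr) for g, pf, pr in rows
                        if pf in pathway_pfams]
        pathway_rows.sort()
        run: list[tuple[int, str, str, float]] = []
        for row in pathway_rows:
            if run and row[0] - run[-1][0] > 2:  # gap of more than one gene
                calls.extend(_emit_operon(org, run))
                run = []
            run.append(row)
        calls.extend(_emit_operon(org, run))
    return calls


def _emit_operon(org: str, run: list) -> list[OperonCall]:
    if len(run) < 2:
        return []
    max_p = max(r[3] for r in run)
    if max_p <= 0.5:
        return []
    genes = tuple(dict.fromkeys(r[1] for r in run))
    pfams = tuple(r[2] for r in run)
    return [OperonCall(org, genes, pfams, max_p)]


# ---------------------------------------------------------------------------
# Markov clustering and organism dereplication


def markov_cluster(
    similarity: np.ndarray,
    expansion: int = 2,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 200,
) -> list[list[int]]:
    """MCL on a symmetric nonnegative similarity matrix; returns clusters
    as sorted index lists forming a partition.

    Classic scheme: add self-loops, column-normalize, then alternate
    expansion (matrix power) and inflation (entrywise power + renormalize)
    with pruning until the matrix is idempotent.
    """
    s = np.asarray(similarity, dtype=float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("similarity matrix must be square and symmetric")
    n = s.shape[0]
    m = s.copy()
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1.0))  # self-loops
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.allclose(m, prev, atol=1e-12):
            break
    # attractors: rows with any positive diagonal-ish mass
    clusters: list[set[int]] = []
    for i in range(n):
        members = set(np.nonzero(m[:, i] > 0)[0].tolist()) | {i} \
            if m[:, i].sum() > 0 else {i}
        merged = False
        for cl in clusters:
            if cl & members:
                cl |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # merge transitively
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((sorted(c) for c in clusters), key=lambda c: c[0])


def dereplicate_organisms(
    marker_identities: dict[tuple[str, str], list[float]],
) -> tuple[list[str], list[list[str]]]:
    """Collapse near-identical organisms: mean marker distance per pair,
    similarity graph, Markov clustering, lexicographically first member
    kept per cluster.

    ``marker_identities`` maps unordered organism pairs to per-marker
    percent identities. Returns (representatives, clusters).
    """
    orgs = sorted({o for pair in marker_identities for o in pair})
    idx = {o: i for i, o in enumerate(orgs)}
    n = len(orgs)
    sim = np.zeros((n, n))
    seen = {}
    for (a, b), idents in marker_identities.items():
        if (b, a) in seen and not np.isclose(seen[(b, a)], np.mean(idents)):
            raise ValueError(f"non-symmetric marker identities for {a}, {b}")
        seen[(a, b)] = float(np.mean(idents))
        mean_dist = 1.0 - float(np.mean(idents)) / 100.0
        sim[idx[a], idx[b]] = sim[idx[b], idx[a]] = 1.0 - mean_dist
    if n == 0:
        return [], []
    if n == 1:
        return orgs, [orgs]
    clusters_idx = markov_cluster(sim)
    clusters = [[orgs[i] for i in cl] for cl in clusters_idx]
    reps = [min(cl) for cl in clusters]
    return sorted(reps), clusters
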