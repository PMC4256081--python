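"""Tree-based detection of concerted evolution.

Neighbor-joining trees of same-type domains across clusters reveal whether
domains group by cluster (BGC-specific clades — the signature of
within-cluster homogenization by gene conversion) or by assembly-line
position (vertical, position-conserved evolution). The NJ implementation
is canonical Saitou–Nei with a fixed smallest-index tie-break and exact
recovery of additive matrices; negative branch lengths are clamped to zero
and flagged. Alignment-column Shannon entropy quantifies per-site
variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np

from .align import global_identity
from .model import DomainAnnotation


@dataclass
class BgcSpecificity:
    per_cluster_fraction: dict[str, float]
    per_cluster_monophyly: dict[str, bool]
    overall_fraction: float

    def __post_init__(self) -> None:
        vals = list(self.per_cluster_fraction.values()) + [self.overall_fraction]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("specificity fractions outside [0, 1]")


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou–Nei Q criterion).

    Ties in Q broken by the smallest (i, j) index pair in the current
    node-creation order; negative branch lengths clamped to 0 with a
    warning. Exact on additive matrices. Returns an unrooted tree (the
    dendropy root is the trifurcating final join).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lb)) for lb in labels]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n
    clamped = False

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _q, i, j = best
        li = 0.5 * get(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = get(i, j) - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes.append(new)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (
                get(i, k) + get(j, k) - get(i, j))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    if min(li, lj, lk) < 0:
        clamped = True
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = max(ln, 0.0)
        root.add_child(nodes[idx])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def typed_domain_leaves(
    corpus, nrps_pks_type: str
) -> tuple[list[DomainAnnotation], dict[str, str]]:
    """All domains of one assembly-line type across a corpus, with leaf
    labels ``cluster_id$domain_id`` (unique corpus-wide) and a label ->
    cluster_id map for :func:`bgc_specificity`."""
    from dataclasses import replace

    leaves, cluster_of = [], {}
    for c in corpus:
        for d in c.domains_in_order():
            if d.nrps_pks_type == nrps_pks_type:
                label = f"{c.cluster_id}${d.domain_id}"
                leaves.append(replace(d, domain_id=label))
                cluster_of[label] = c.cluster_id
    return leaves, cluster_of


def domain_distance_matrix(
    domains: list[DomainAnnotation],
) -> tuple[np.ndarray, list[str]]:
    """p-distance-style matrix d = 1 − identity/100 from pairwise global
    amino-acid alignments of same-type domains."""
    if len(domains) < 3:
        raise ValueError("need >= 3 domains for a distance matrix")
    labels = [d.domain_id for d in domains]
    n = len(domains)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(domains[i].aa_seq, domains[j].aa_seq)
            m[i, j] = m[j, i] = 1.0 - ident / 100.0
    return m, labels


# ---------------------------------------------------------------------------
# BGC-specific branching


def bgc_specificity(
    tree: dendropy.Tree, cluster_of: dict[str, str]
) -> BgcSpecificity:
    """Fraction of leaves whose nearest tree neighbor (patristic distance)
    belongs to the same cluster, plus per-cluster monophyly on the
    unrooted tree.

    A leaf with tied nearest neighbors counts as cluster-specific only if
    every tied neighbor is from the same cluster. ``cluster_of`` maps leaf
    labels to cluster ids.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    clusters = {cluster_of[lb] for lb in leaves}
    if len(clusters) < 2:
        raise ValueError("specificity undefined on a single-cluster tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    specific: dict[str, list[bool]] = {c: [] for c in clusters}
    for lb in leaves:
        dists = []
        for other in leaves:
            if other == lb:
                continue
            dists.append((pdm.patristic_distance(taxa[lb], taxa[other]),
                          other))
        dmin = min(x[0] for x in dists)
        tied = [x[1] for x in dists if math.isclose(x[0], dmin,
                                                    rel_tol=1e-9,
                                                    abs_tol=1e-12)]
        ok = all(cluster_of[t] == cluster_of[lb] for t in tied)
        specific[cluster_of[lb]].append(ok)
    bip_sets = _bipartition_leafsets(tree)
    all_leaves = frozenset(leaves)
    mono = {}
    for c in clusters:
        members = frozenset(lb for lb in leaves if cluster_of[lb] == c)
        mono[c] = (len(members) == 1 or members in bip_sets
                   or (all_leaves - members) in bip_sets)
    per_cluster = {c: float(np.mean(v)) for c, v in specific.items()}
    overall = float(np.mean([x for v in specific.values() for x in v]))
    return BgcSpecificity(per_cluster, mono, overall)


def _bipartition_leafsets(tree: dendropy.Tree) -> set[frozenset]:
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.add(under)
    return out


# ---------------------------------------------------------------------------
# alignment-column entropy


def column_entropy(
    msa: list[str], exclude_gaps: bool = True, gap_chars: str = "-.",
    indel_flag_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropy (bits) per alignment column from amino-acid
    frequencies.

    Gaps are excluded from the frequencies by default; columns whose gap
    fraction exceeds ``indel_flag_fraction`` are flagged as indel-rich
    (entropy still reported where computable; NaN for empty columns).
    Returns (entropies, indel_rich_flags).
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(row) != L for row in msa):
        raise ValueError("alignment rows differ in length")
    ent = np.zeros(L)
    flags = np.zeros(L, dtype=bool)
    for j in range(L):
        col = [row[j] for row in msa]
        gaps = sum(c in gap_chars for c in col)
        flags[j] = gaps / len(col) > indel_flag_fraction
        if exclude_gaps:
            col = [c for c in col if c not in gap_chars]
        if not col:
            ent[j] = np.nan
            continue
        _vals, counts = np.unique(col, return_counts=True)
        f = counts / counts.sum()
        ent[j] = float(-(f * np.log2(f)).sum())
    return ent, flags


# ---------------------------------------------------------------------------
# newick / PHYLIP I/O and bootstrap support


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def write_phylip(d: np.ndarray, labels: list[str]) -> str:
    buf = StringIO()
    buf.write(f"{len(labels)}\n")
    for i, lb in enumerate(labels):
        row = " ".join(f"{x:.6f}" for x in d[i])
        buf.write(f"{lb}  {row}\n")
    return buf.getvalue()


def read_phylip(text: str) -> tuple[np.ndarray, list[str]]:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return np.asarray(rows), labels


def bootstrap_support(
    alignment: dict[str, str], n_replicates: int = 100, seed: int = 0
) -> dict[frozenset, float]:
    """Split support by column resampling: NJ on p-distances of each
    resampled alignment; returns bipartition leafset -> support fraction."""
    labels = sorted(alignment)
    L = len(alignment[labels[0]])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        res = {lb: "".join(alignment[lb][c] for c in cols) for lb in labels}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = res[labels[i]], res[labels[j]]
                diff = sum(x != y for x, y in zip(a, b))
                d[i, j] = d[j, i] = diff / L
        t = nj_tree(d, labels)
        for bp in _bipartition_leafsets(t):
            if 1 < len(bp) < n:
                counts[bp] = counts.get(bp, 0) + 1
    return {bp: c / n_replicates for bp, c in counts.items()}
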