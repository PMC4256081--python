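"""Shared sub-cluster detection and the sharing network.

A sub-cluster definition is a small set of genes (from a source cluster)
that together encode a chemical moiety. A target cluster shares the
sub-cluster when enough of its genes have sufficiently similar protein
hits: >=75% of genes at >45% mean identity, >=50% at >50%, or >=25% at
>=70% — optionally overridden per sub-cluster type. The sharing network
has clusters as nodes (sized by how many distinct sub-clusters they share)
and one edge per shared sub-cluster between a cluster pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .align import global_identity
from .model import Corpus, GeneCluster

#: (min gene fraction, min mean identity %) — any rule qualifying emits an
#: edge; rules checked from most to least gene-inclusive
DEFAULT_RULES: tuple[tuple[float, float], ...] = (
    (0.75, 45.0),
    (0.50, 50.0),
    (0.25, 70.0),
)


@dataclass
class SubclusterDef:
    subcluster_id: str
    type_label: str
    source_cluster_id: str
    gene_ids: tuple[str, ...]
    moiety: str = ""
    cutoff_override: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("sub-cluster needs >= 2 genes")
        rules = self.cutoff_override or ()
        if any(not (0 < f <= 1) for f, _i in rules):
            raise ValueError("gene fractions must lie in (0, 1]")


@dataclass
class SharingEdge:
    pair: tuple[str, str]
    subcluster_id: str
    rule_satisfied: tuple[float, float]
    gene_fraction: float
    mean_identity: float

    def __post_init__(self) -> None:
        f_min, i_min = self.rule_satisfied
        if self.gene_fraction < f_min - 1e-12:
            raise ValueError("recorded gene fraction below the fired rule")
        if self.mean_identity <= i_min:
            raise ValueError("recorded identity below the fired rule")


def detect_shared_subcluster(
    subdef: SubclusterDef,
    source: GeneCluster,
    target: GeneCluster,
    rules: tuple[tuple[float, float], ...] = DEFAULT_RULES,
) -> Optional[SharingEdge]:
    """Does ``target`` carry the sub-cluster defined on ``source``?

    Each definition gene gets one best protein hit in the target (greedy
    one-to-one by descending identity). For each rule the qualifying genes
    are those whose hit clears the rule's identity floor; mean identity is
    taken over qualifying genes only. The strongest fired rule (checked in
    definition order, overrides first) is recorded.
    """
    if target.cluster_id == subdef.source_cluster_id:
        return None
    def_genes = [source.gene(g) for g in subdef.gene_ids]
    cands = []
    for dg in def_genes:
        for tg in target.genes:
            if not dg.protein or not tg.protein:
                continue
            cands.append((global_identity(dg.protein, tg.protein),
                          dg.gene_id, tg.gene_id))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_hit: dict[str, float] = {}
    used_target: set[str] = set()
    for ident, dgid, tgid in cands:
        if dgid in best_hit or tgid in used_target:
            continue
        best_hit[dgid] = ident
        used_target.add(tgid)
    n = len(def_genes)
    active_rules = subdef.cutoff_override or rules
    for f_min, i_min in active_rules:
        qual = [v for v in best_hit.values() if v > i_min]
        if not qual:
            continue
        frac = len(qual) / n
        mean_id = sum(qual) / len(qual)
        if frac >= f_min and mean_id > i_min:
            return SharingEdge(
                (subdef.source_cluster_id, target.cluster_id),
                subdef.subcluster_id, (f_min, i_min), frac, mean_id)
    return None


def build_sharing_network(
    corpus: Corpus,
    defs: list[SubclusterDef],
    rules: tuple[tuple[float, float], ...] = DEFAULT_RULES,
) -> nx.MultiGraph:
    """Sharing network: one node per cluster (attribute ``n_shared`` =
    number of distinct sub-clusters shared with any other cluster), one
    edge per (cluster pair, sub-cluster). Deterministic ordering."""
    by_id = {c.cluster_id: c for c in corpus}
    g = nx.MultiGraph()
    for c in sorted(by_id):
        g.add_node(c, n_shared=0)
    carriers: dict[str, list[str]] = {}
    edges_raw: list[SharingEdge] = []
    for subdef in sorted(defs, key=lambda s: s.subcluster_id):
        source = by_id[subdef.source_cluster_id]
        found = [subdef.source_cluster_id]
        for cid in sorted(by_id):
            edge = detect_shared_subcluster(subdef, source, by_id[cid], rules)
            if edge is not None:
                found.append(cid)
                edges_raw.append(edge)
        carriers[subdef.subcluster_id] = sorted(found)
    for sub_id, members in sorted(carriers.items()):
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j], subcluster_id=sub_id)
    shared_by_node: dict[str, set[str]] = {c: set() for c in by_id}
    for sub_id, members in carriers.items():
        if len(members) >= 2:
            for mem in members:
                shared_by_node[mem].add(sub_id)
    for c, subs in shared_by_node.items():
        g.nodes[c]["n_shared"] = len(subs)
    return g


def network_to_sif(g: nx.MultiGraph) -> str:
    lines = []
    for u, v, data in sorted(g.edges(data=True),
                             key=lambda e: (e[0], e[1],
                                            e[2].get("subcluster_id", ""))):
        lines.append(f"{u}\t{data.get('subcluster_id', 'shared')}\t{v}")
    isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
    lines.extend(isolated)
    return "\n".join(lines) + ("\n" if lines else "")


def node_attribute_table(g: nx.MultiGraph) -> str:
    lines = ["cluster_id\tn_shared"]
    for n in sorted(g.nodes):
        lines.append(f"{n}\t{g.nodes[n]['n_shared']}")
    return "\n".join(lines) + "\n"


def write_graphml(g: nx.MultiGraph, path) -> None:
    nx.write_graphml(g, path)
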