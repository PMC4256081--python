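"""Evolutionary-mode features for multimodular NRPS/PKS clusters.

Per cluster: empirical p-values for each domain's best within-cluster
same-type match (against the corpus-wide distribution of such matches),
the internal similarity index (mean 1−p; high in concerted/repetitive
clusters), the vertical evolution index (are a cluster's domains'
best relatives found in otherwise-similar clusters, or recruited from
unrelated ones?), and topology features of the intra-cluster domain
similarity network. A PCA over the feature table separates evolutionary
modes; "inverse p-value" is realized as 1−p throughout (bounded and
order-preserving).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .align import global_identity
from .model import Corpus, DomainAnnotation, GeneCluster
from .similarity import IdentityBackground, bgc_jaccard, domain_identity_background

NETWORK_IDENTITY_THRESHOLD = 50.0
TOP_HITS = 10

FEATURE_NAMES = [
    "avg_clustering_coefficient", "avg_sequence_similarity",
    "graph_transitivity", "n_cliques_2", "n_cliques_3", "n_cliques_4",
    "n_connected_components_50", "avg_neighbor_degree", "n_pfam_types",
    "n_domains", "avg_domains_per_gene", "mean_best_pair_identity",
    "se_best_pair_identity", "mean_internal_index", "se_internal_index",
    "internal_similarity_index", "vertical_evolution_index",
]


def domain_type(d: DomainAnnotation) -> str:
    """Assembly-line role when annotated, else the Pfam family."""
    return d.nrps_pks_type or d.pfam_id


@dataclass
class InternalHomology:
    domain_id: str
    best_within_identity: float
    p_internal: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_internal <= 1.0):
            raise ValueError("p_internal outside (0, 1]")


def _empirical_upper_p(background: np.ndarray, x: float) -> float:
    """(r+1)/(N+1) upper-tail estimator; never exactly zero."""
    r = int(np.sum(background >= x))
    return (r + 1) / (len(background) + 1)


def within_cluster_best_identities(
    cluster: GeneCluster,
) -> dict[str, tuple[str, float]]:
    """Per domain with a same-type partner in the cluster: its best
    within-cluster identity, keyed by domain_id -> (type, identity)."""
    by_type: dict[str, list[DomainAnnotation]] = {}
    for d in cluster.domains_in_order():
        by_type.setdefault(domain_type(d), []).append(d)
    out: dict[str, tuple[str, float]] = {}
    for t, ds in by_type.items():
        if len(ds) < 2:
            continue
        for d in ds:
            best = max(
                global_identity(d.aa_seq, o.aa_seq)
                for o in ds if o.domain_id != d.domain_id
            )
            out[d.domain_id] = (t, best)
    return out


def internal_background(corpus: Corpus) -> dict[str, np.ndarray]:
    """Corpus-wide distribution of within-cluster best same-type
    identities, per domain type."""
    acc: dict[str, list[float]] = {}
    for c in corpus:
        for _did, (t, ident) in within_cluster_best_identities(c).items():
            acc.setdefault(t, []).append(ident)
    return {t: np.sort(np.asarray(v)) for t, v in acc.items()}


def internal_homology(
    cluster: GeneCluster, background: dict[str, np.ndarray]
) -> list[InternalHomology]:
    """Empirical p of each domain's best within-cluster same-type match;
    domains with no same-type partner are omitted (undefined)."""
    out = []
    for did, (t, ident) in sorted(
        within_cluster_best_identities(cluster).items()
    ):
        bg = background.get(t)
        if bg is None or len(bg) == 0:
            warnings.warn(f"no background for domain type {t!r}")
            continue
        out.append(InternalHomology(did, ident, _empirical_upper_p(bg, ident)))
    return out


def internal_similarity_index(
    homologies: list[InternalHomology],
) -> Optional[float]:
    """Mean of 1 − p over defined domains; None when nothing is defined."""
    if not homologies:
        return None
    return float(np.mean([1.0 - h.p_internal for h in homologies]))


# ---------------------------------------------------------------------------
# vertical evolution index


class CorpusDomainIndex:
    """Corpus-level caches shared by VEI and the feature table: cross-
    cluster same-type identities, per-type backgrounds, cluster-pair
    similarities."""

    def __init__(self, corpus: Corpus,
                 cluster_similarity_fn: Optional[Callable] = None):
        self.corpus = corpus
        self.by_id = {c.cluster_id: c for c in corpus}
        self.background: Optional[IdentityBackground] = None
        if cluster_similarity_fn is None:
            self.background = domain_identity_background(corpus)
            bg = self.background

            def _default_sim(a: GeneCluster, b: GeneCluster) -> float:
                return bgc_jaccard(a, b, bg).jaccard

            cluster_similarity_fn = _default_sim
        self.cluster_similarity_fn = cluster_similarity_fn
        # cross-cluster same-type domain identities
        self._domains: list[tuple[str, str, DomainAnnotation]] = [
            (c.cluster_id, domain_type(d), d)
            for c in corpus for d in c.domains_in_order()
        ]
        self._hits: dict[str, list[tuple[float, str]]] = {}
        self._identity_dist: dict[str, np.ndarray] = {}
        by_type: dict[str, list[tuple[str, DomainAnnotation]]] = {}
        for cid, t, d in self._domains:
            by_type.setdefault(t, []).append((cid, d))
        for t, members in by_type.items():
            vals = []
            for i in range(len(members)):
                hits_i = []
                for j in range(len(members)):
                    if i == j or members[i][0] == members[j][0]:
                        continue
                    ident = global_identity(members[i][1].aa_seq,
                                            members[j][1].aa_seq)
                    hits_i.append((ident, members[j][0]))
                    if j > i:
                        vals.append(ident)
                hits_i.sort(key=lambda h: (-h[0], h[1]))
                self._hits[(members[i][0], members[i][1].domain_id)] = hits_i
            self._identity_dist[t] = np.sort(np.asarray(vals))
        # cluster-pair similarity distribution
        self._sim: dict[frozenset, float] = {}
        ids = sorted(self.by_id)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                s = self.cluster_similarity_fn(self.by_id[ids[i]],
                                               self.by_id[ids[j]])
                self._sim[frozenset((ids[i], ids[j]))] = s
        self._sim_dist = np.sort(np.asarray(list(self._sim.values())))

    def top_hits(self, cluster_id: str, domain_id: str, k: int = TOP_HITS):
        return self._hits.get((cluster_id, domain_id), [])[:k]

    def p_identity(self, dtype: str, identity: float) -> float:
        dist = self._identity_dist.get(dtype, np.asarray([]))
        return _empirical_upper_p(dist, identity)

    def p_similarity(self, cid_a: str, cid_b: str) -> float:
        s = self._sim[frozenset((cid_a, cid_b))]
        return _empirical_upper_p(self._sim_dist, s)


def vertical_evolution_index(
    cluster: GeneCluster, index: CorpusDomainIndex, top_k: int = TOP_HITS
) -> Optional[float]:
    """Mean over domains and their top cross-cluster hits of
    p_identity − p_similarity.

    Positive: hits are in exceptionally similar clusters while hit
    identities are corpus-typical (vertical coherence). Negative: hits are
    exceptionally similar sequences sitting in unremarkable clusters
    (promiscuous domain recruitment). Range [−1, 1].
    """
    if len(index.corpus) < 3:
        raise ValueError("VEI needs a corpus of >= 3 clusters")
    deltas = []
    for d in cluster.domains_in_order():
        for ident, other_cid in index.top_hits(cluster.cluster_id,
                                               d.domain_id, top_k):
            p_id = index.p_identity(domain_type(d), ident)
            p_sim = index.p_similarity(cluster.cluster_id, other_cid)
            deltas.append(p_id - p_sim)
    if not deltas:
        return None
    return float(np.mean(deltas))


# ---------------------------------------------------------------------------
# domain similarity network topology


def domain_network_features(cluster: GeneCluster) -> dict[str, float]:
    """Topology of the intra-cluster domain similarity network, thresholded
    at >50% identity (weighted mean identity reported separately)."""
    doms = cluster.domains_in_order()
    if len(doms) < 2:
        return {k: 0.0 for k in FEATURE_NAMES[:8]} | {"singleton": 1.0}
    idents = {}
    for i in range(len(doms)):
        for j in range(i + 1, len(doms)):
            idents[(i, j)] = global_identity(doms[i].aa_seq, doms[j].aa_seq)
    g = nx.Graph()
    g.add_nodes_from(range(len(doms)))
    for (i, j), v in idents.items():
        if v > NETWORK_IDENTITY_THRESHOLD:
            g.add_edge(i, j, weight=v)
    n3 = sum(1 for _ in _cliques_of_size(g, 3))
    n4 = sum(1 for _ in _cliques_of_size(g, 4))
    and_vals = list(nx.average_neighbor_degree(g).values())
    return {
        "avg_clustering_coefficient": float(nx.average_clustering(g)),
        "avg_sequence_similarity": float(np.mean(list(idents.values()))),
        "graph_transitivity": float(nx.transitivity(g)),
        "n_cliques_2": float(g.number_of_edges()),
        "n_cliques_3": float(n3),
        "n_cliques_4": float(n4),
        "n_connected_components_50": float(nx.number_connected_components(g)),
        "avg_neighbor_degree": float(np.mean(and_vals)) if and_vals else 0.0,
        "singleton": 0.0,
    }


def _cliques_of_size(g: nx.Graph, k: int):
    """All complete subgraphs of exactly k nodes."""
    from itertools import combinations

    for nodes in combinations(sorted(g.nodes), k):
        if all(g.has_edge(a, b) for a, b in combinations(nodes, 2)):
            yield nodes


# ---------------------------------------------------------------------------
# feature table and PCA


def feature_table(
    corpus: Corpus, index: Optional[CorpusDomainIndex] = None
) -> pd.DataFrame:
    """One row per cluster with the named evolutionary-mode features."""
    if index is None:
        index = CorpusDomainIndex(corpus)
    bg = internal_background(corpus)
    rows = {}
    for c in corpus:
        feats = domain_network_features(c)
        feats.pop("singleton", None)
        homol = internal_homology(c, bg)
        best = [h.best_within_identity for h in homol]
        inv = [1.0 - h.p_internal for h in homol]
        isi = internal_similarity_index(homol)
        vei = vertical_evolution_index(c, index)
        n_genes = max(len(c.genes), 1)
        feats.update({
            "n_pfam_types": float(len({d.pfam_id for d in c.domains})),
            "n_domains": float(len(c.domains)),
            "avg_domains_per_gene": len(c.domains) / n_genes,
            "mean_best_pair_identity": float(np.mean(best)) if best else 0.0,
            "se_best_pair_identity":
                float(np.std(best, ddof=1) / np.sqrt(len(best)))
                if len(best) > 1 else 0.0,
            "mean_internal_index": float(np.mean(inv)) if inv else 0.0,
            "se_internal_index":
                float(np.std(inv, ddof=1) / np.sqrt(len(inv)))
                if len(inv) > 1 else 0.0,
            "internal_similarity_index": isi if isi is not None else 0.0,
            "vertical_evolution_index": vei if vei is not None else 0.0,
        })
        rows[c.cluster_id] = feats
    return pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # components x features
    scores: pd.DataFrame  # clusters x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        r = self.explained_variance_ratio
        if np.any(r < -1e-12):
            raise ValueError("negative explained variance ratio")


def pca(features: pd.DataFrame, standardize: bool = True,
        n_components: Optional[int] = None) -> PCAResult:
    """PCA of the feature table (z-scored columns by default); constant
    columns dropped with a warning. Sign convention: each component's
    largest-magnitude loading is positive."""
    x = features.copy()
    const = x.columns[x.std(ddof=0) == 0]
    if len(const):
        warnings.warn(f"dropping constant feature columns: {list(const)}")
        x = x.drop(columns=const)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 clusters and >= 2 varying features")
    vals = x.to_numpy(dtype=float)
    if standardize:
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(vals)
    loadings = model.components_
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=comp_names, columns=x.columns),
        scores=pd.DataFrame(scores, index=features.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
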