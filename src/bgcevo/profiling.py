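"""Phylogenetic profiling of consecutive Pfam domains.

For each cluster, a domain × organism matrix holds the percent identity of
every domain to its best same-Pfam homolog in each organism's clusters
(0 when the organism has none). Pearson correlations between domain
profiles, reordered by hierarchical clustering, expose runs of co-evolving
adjacent domains (sub-cluster motifs); motif significance is a 1-df χ²
goodness-of-fit of co-evolving vs non-co-evolving occurrence counts, with
Bonferroni correction over the motifs tested.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .align import global_identity
from .model import Corpus, GeneCluster

CC_CUTOFFS = (0.5, 0.65, 0.8)


@dataclass
class DomainOrganismMatrix:
    cluster_id: str
    domain_ids: list[str]
    pfam_ids: list[str]
    organism_ids: list[str]
    values: np.ndarray  # identities in [0, 100]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.domain_ids), len(self.organism_ids)):
            raise ValueError("matrix shape mismatch")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("identities outside [0, 100]")
        self.values = v


@dataclass
class MotifResult:
    pfam_ids: tuple[str, ...]
    n_coevolving: int
    n_possible_noncoevolving: int
    chi2: float
    p: float
    p_bonferroni: float

    def __post_init__(self) -> None:
        if len(self.pfam_ids) < 2:
            raise ValueError("motif needs >= 2 domains")
        if self.p_bonferroni < self.p - 1e-15:
            raise ValueError("p_bonferroni < p")


def build_identity_matrix(
    cluster: GeneCluster, corpus: Corpus, organisms: list[str]
) -> DomainOrganismMatrix:
    """Max identity of each cluster domain to same-Pfam domains inside each
    organism's clusters (the query's own organism excluded by construction
    only when it hosts no other clusters; self-cluster always excluded)."""
    by_org_pfam: dict[tuple[str, str], list[str]] = {}
    for other in corpus:
        if other.cluster_id == cluster.cluster_id:
            continue
        for d in other.domains:
            by_org_pfam.setdefault((other.organism_id, d.pfam_id), []).append(
                d.aa_seq)
    doms = cluster.domains_in_order()
    known_orgs = {c.organism_id for c in corpus}
    for org in organisms:
        if org not in known_orgs:
            warnings.warn(f"organism {org!r} absent from corpus; zero column")
    values = np.zeros((len(doms), len(organisms)))
    for i, d in enumerate(doms):
        for j, org in enumerate(organisms):
            seqs = by_org_pfam.get((org, d.pfam_id), [])
            if seqs:
                values[i, j] = max(
                    global_identity(d.aa_seq, s) for s in seqs)
    return DomainOrganismMatrix(
        cluster.cluster_id, [d.domain_id for d in doms],
        [d.pfam_id for d in doms], list(organisms), values)


def correlate_and_reorder(
    m: DomainOrganismMatrix,
) -> tuple[np.ndarray, list[int]]:
    """Pearson correlation matrix of domain profiles, rows/columns reordered
    by average-linkage hierarchical clustering (Euclidean distance on
    correlation rows). Zero-variance profiles get correlation 0.

    Returns (reordered correlation matrix, row order as original indices).
    """
    n, n_org = m.values.shape
    if n_org < 2:
        raise ValueError("need >= 2 organisms")
    if n < 2:
        raise ValueError("need >= 2 domains")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m.values)
    zero_var = np.std(m.values, axis=1) == 0
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, np.where(zero_var, 0.0, 1.0))
    dist = squareform(
        np.sqrt(np.maximum(
            ((corr[:, None, :] - corr[None, :, :]) ** 2).sum(-1), 0)),
        checks=False)
    order = (list(leaves_list(linkage(dist, method="average")))
             if n > 2 else [0, 1])
    order = [int(i) for i in order]
    return corr[np.ix_(order, order)], order


def extract_motifs(
    reordered: np.ndarray, row_order: list[int], pfam_ids: list[str],
    cc_cutoff: float = 0.5,
) -> list[tuple[str, ...]]:
    """Maximal runs of consecutive first-offset-diagonal correlations above
    the cutoff, expanded into all contiguous sub-runs of length >= 2.

    ``pfam_ids`` are in the original domain order. Because leaf order
    within a block of highly correlated rows is arbitrary, each run's
    member domains are mapped back to their genomic order before sub-run
    expansion.
    """
    n = reordered.shape[0]
    diag = [reordered[k, k + 1] for k in range(n - 1)]
    motifs: list[tuple[str, ...]] = []
    run_start = None
    for k in range(n - 1):
        if diag[k] > cc_cutoff:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None:
                motifs.extend(
                    _sub_runs(sorted(row_order[run_start : k + 1]), pfam_ids))
                run_start = None
    if run_start is not None:
        motifs.extend(_sub_runs(sorted(row_order[run_start : n]), pfam_ids))
    return motifs


def _sub_runs(indices: list[int], pfam_ids: list[str]) -> list[tuple[str, ...]]:
    pf = [pfam_ids[i] for i in indices]
    out = []
    for size in range(2, len(pf) + 1):
        for s in range(len(pf) - size + 1):
            out.append(tuple(pf[s : s + size]))
    return out


def motif_occurs(cluster: GeneCluster, motif: tuple[str, ...]) -> bool:
    """A motif occurs in a cluster when its Pfam multiset appears as a
    consecutive run of the cluster's domain order (order-insensitive: the
    clustering leaf order within a correlated block is arbitrary)."""
    seq = cluster.domain_pfam_order()
    k = len(motif)
    want = Counter(motif)
    for s in range(len(seq) - k + 1):
        if Counter(seq[s : s + k]) == want:
            return True
    return False


def chi2_equal_counts(a: int, b: int) -> tuple[float, float]:
    """1-df goodness-of-fit of (a, b) against equal expectation:
    χ² = (a−b)²/(a+b)."""
    if a + b == 0:
        raise ValueError("a + b must be positive")
    stat = (a - b) ** 2 / (a + b)
    return float(stat), float(chi2.sf(stat, df=1))


def test_motif_significance(
    candidates_per_cluster: dict[str, list[tuple[str, ...]]],
    corpus: Corpus,
    alpha: float = 0.001,
) -> list[MotifResult]:
    """Pool candidate motifs across the corpus and χ²-test each unique
    motif: a = clusters where the motif occurs and passed the correlation
    cutoff, b = clusters where it occurs but did not pass.

    ``candidates_per_cluster`` maps cluster_id to the motifs extracted from
    that cluster's reordered correlation matrix.
    """
    unique: dict[frozenset, tuple[str, ...]] = {}
    passed: dict[frozenset, set[str]] = {}
    for cid, motifs in candidates_per_cluster.items():
        for m in motifs:
            key = frozenset(Counter(m).items())
            unique.setdefault(key, m)
            passed.setdefault(key, set()).add(cid)
    counts: dict[frozenset, tuple[int, int]] = {}
    for key in unique:
        a = b = 0
        for cluster in corpus:
            if not motif_occurs(cluster, unique[key]):
                continue
            if cluster.cluster_id in passed[key]:
                a += 1
            else:
                b += 1
        if a + b == 0:
            warnings.warn(f"motif {unique[key]} occurs nowhere; skipped")
            continue
        counts[key] = (a, b)
    n_tests = len(counts)  # Bonferroni family: motifs actually testable
    results = []
    for key in sorted(counts, key=lambda k: unique[k]):
        a, b = counts[key]
        stat, p = chi2_equal_counts(a, b)
        p_bonf = min(1.0, p * n_tests)
        results.append(MotifResult(unique[key], a, b, stat, p, p_bonf))
    return results


test_motif_significance.__test__ = False  # not a pytest test


def profile_corpus(
    corpus: Corpus, cc_cutoff: float = 0.5, alpha: float = 0.001
) -> tuple[list[MotifResult], dict[str, list[tuple[str, ...]]]]:
    """Full profiling pass: identity matrices, correlation reordering,
    motif extraction and significance testing for every cluster with >= 2
    domains."""
    organisms = sorted({c.organism_id for c in corpus})
    candidates: dict[str, list[tuple[str, ...]]] = {}
    for cluster in corpus:
        if len(cluster.domains) < 2 or len(organisms) < 2:
            continue
        m = build_identity_matrix(cluster, corpus, organisms)
        corr, order = correlate_and_reorder(m)
        motifs = extract_motifs(corr, order, m.pfam_ids, cc_cutoff)
        if motifs:
            candidates[cluster.cluster_id] = motifs
    return test_motif_significance(candidates, corpus, alpha), candidates


def motifs_to_frame(results: list[MotifResult]) -> pd.DataFrame:
    """Table mirroring the published layout: co-evolving and
    non-co-evolving counts, χ², p-values, Pfam-ID string."""
    return pd.DataFrame(
        {
            "n_coevolving": [r.n_coevolving for r in results],
            "n_noncoevolving": [r.n_possible_noncoevolving for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "pfam_ids": [";".join(r.pfam_ids) for r in results],
        }
    )
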