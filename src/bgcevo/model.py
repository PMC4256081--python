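"""Shared domain types for the BGC-evolution pipeline.

A :class:`GeneCluster` is the universal unit of comparison: a genomic locus
with an ordered list of genes, per-gene protein sequences, and Pfam-style
domain annotations. Coordinates are 0-based half-open on the nucleotide
sequence throughout the package; GenBank's 1-based inclusive convention is
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

VALID_NT = set("ACGTN")

#: Domain roles in multimodular NRPS/PKS assembly lines.
NRPS_PKS_TYPES = ("KS", "AT", "C", "A", "T", "other")


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene within a cluster (0-based half-open coords)."""

    gene_id: str
    start: int
    end: int
    strand: int  # +1 / -1
    protein: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.gene_id!r}: strand must be +1/-1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainAnnotation:
    """One Pfam-annotated protein domain inside a cluster.

    ``order_index`` is the domain's left-to-right rank among all of the
    cluster's domains (by genomic midpoint). ``aa_start``/``aa_end`` locate
    the domain within its gene's protein (optional plumbing used by the
    simulator's gene-conversion operator).
    """

    domain_id: str
    pfam_id: str
    gene_id: str
    order_index: int
    aa_seq: str
    nrps_pks_type: Optional[str] = None
    module_index: Optional[int] = None
    aa_start: Optional[int] = None
    aa_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"domain {self.domain_id!r}: empty aa_seq")
        if self.nrps_pks_type is not None and self.nrps_pks_type not in NRPS_PKS_TYPES:
            raise ValueError(
                f"domain {self.domain_id!r}: bad nrps_pks_type {self.nrps_pks_type!r}"
            )


@dataclass
class GeneCluster:
    """A biosynthetic (or primary-metabolic) gene cluster."""

    cluster_id: str
    organism_id: str
    genes: list[Gene] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)
    sequence: Optional[str] = None
    class_label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sequence is not None:
            bad = set(self.sequence) - VALID_NT
            if bad:
                raise ValueError(
                    f"cluster {self.cluster_id!r}: invalid nucleotides {sorted(bad)}"
                )
            for g in self.genes:
                if g.start < 0 or g.end > len(self.sequence):
                    raise ValueError(
                        f"cluster {self.cluster_id!r}: gene {g.gene_id!r} "
                        f"[{g.start},{g.end}) outside sequence of length "
                        f"{len(self.sequence)}"
                    )
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"cluster {self.cluster_id!r}: genes not sorted by start")
        gene_ids = {g.gene_id for g in self.genes}
        if len(gene_ids) != len(self.genes):
            raise ValueError(f"cluster {self.cluster_id!r}: duplicate gene ids")
        dom_ids = [d.domain_id for d in self.domains]
        if len(set(dom_ids)) != len(dom_ids):
            raise ValueError(f"cluster {self.cluster_id!r}: duplicate domain ids")
        for d in self.domains:
            if d.gene_id not in gene_ids:
                raise ValueError(
                    f"cluster {self.cluster_id!r}: domain {d.domain_id!r} "
                    f"references unknown gene {d.gene_id!r}"
                )
        order = sorted(d.order_index for d in self.domains)
        if order != list(range(len(self.domains))):
            raise ValueError(
                f"cluster {self.cluster_id!r}: domain order_index not 0..n-1"
            )

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return max((g.end for g in self.genes), default=0)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def domains_in_order(self) -> list[DomainAnnotation]:
        return sorted(self.domains, key=lambda d: d.order_index)

    def domain_pfam_order(self) -> list[str]:
        return [d.pfam_id for d in self.domains_in_order()]

    def copy(self) -> "GeneCluster":
        c = GeneCluster.__new__(GeneCluster)
        c.cluster_id = self.cluster_id
        c.organism_id = self.organism_id
        c.genes = list(self.genes)
        c.domains = list(self.domains)
        c.sequence = self.sequence
        c.class_label = self.class_label
        return c


def assign_order_index(
    cluster_genes: Sequence[Gene], domains: Iterable[DomainAnnotation]
) -> list[DomainAnnotation]:
    """Re-assign ``order_index`` by the genomic midpoint of each domain's gene
    (ties broken by aa_start, then domain_id)."""
    gene_pos = {g.gene_id: (g.start + g.end) / 2 for g in cluster_genes}
    ranked = sorted(
        domains,
        key=lambda d: (gene_pos[d.gene_id], d.aa_start or 0, d.domain_id),
    )
    return [replace(d, order_index=i) for i, d in enumerate(ranked)]


@dataclass
class OrganismDistanceTable:
    """Symmetric pairwise organism distances in [0, 1] (e.g. marker-gene
    distances standing in for 16S divergence)."""

    organism_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.organism_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match organism list")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.distances = d
        self._index = {o: i for i, o in enumerate(self.organism_ids)}

    def distance(self, a: str, b: str) -> float:
        return float(self.distances[self._index[a], self._index[b]])


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length chemical fingerprint as a bit vector (e.g. FP2)."""

    bits: tuple[int, ...]
    n_bits: int

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")
        if len(self.bits) != self.n_bits:
            raise ValueError("bit vector length != n_bits")

    @classmethod
    def from_hex(cls, hexstring: str, n_bits: Optional[int] = None) -> "Fingerprint":
        raw = bin(int(hexstring, 16))[2:].zfill(len(hexstring) * 4)
        if n_bits is None:
            n_bits = len(raw)
        bits = tuple(int(c) for c in raw[-n_bits:].zfill(n_bits))
        return cls(bits=bits, n_bits=n_bits)

    def popcount(self) -> int:
        return sum(self.bits)


Corpus = list[GeneCluster]


def sort_corpus(corpus: Iterable[GeneCluster]) -> Corpus:
    out = sorted(corpus, key=lambda c: c.cluster_id)
    ids = [c.cluster_id for c in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cluster_id in corpus")
    return out
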