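"""Percent-identity computation and best-hit search.

One internal aligner serves every stage of the pipeline, replacing the
MUSCLE/blastn/blastp mix that a cluster-scale study would use externally:

* ``global_identity`` — Needleman–Wunsch global alignment via Biopython's
  ``PairwiseAligner``. Nucleotide scores: match +1, mismatch −1, gap open −5,
  gap extend −1. Amino acids: BLOSUM62, gap open −11, extend −1.
* ``infix_identity`` — semi-global (query-in-target) placement under unit
  edit costs via edlib, used where a short query must be located inside a
  long subject (the blast-like dialect; see :mod:`bgcevo.blocks`).

Identity is always matches / alignment-columns × 100, gaps included in the
denominator, and an ambiguous ``N`` never counts as a match. An adapter for
external 12-column tabular search output is provided for scale.
"""

from __future__ import annotations

import csv
import functools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@functools.lru_cache(maxsize=4)
def _aligner(alphabet: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if alphabet == "nt":
        al.match_score = 1.0
        al.mismatch_score = -1.0
        al.open_gap_score = -5.0
        al.extend_gap_score = -1.0
    elif alphabet == "aa":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return al


def _identity_from_alignment(aln: Align.Alignment, ambiguous: str) -> float:
    a, b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "-" and x not in ambiguous
    )
    return 100.0 * matches / len(a)


@functools.lru_cache(maxsize=200_000)
def _global_identity_cached(a: str, b: str, alphabet: str) -> float:
    aln = _aligner(alphabet).align(a, b)[0]
    return _identity_from_alignment(aln, "N" if alphabet == "nt" else "X")


def global_identity(a: str, b: str, alphabet: str = "aa") -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``.

    Deterministic (first optimal alignment under Biopython's traceback
    order) and symmetric; 100.0 iff the sequences are equal.
    """
    if not a or not b:
        raise ValueError("global_identity requires nonempty sequences")
    # canonical order for symmetry and cache hits
    if b < a:
        a, b = b, a
    return _global_identity_cached(a, b, alphabet)


def infix_identity(query: str, target: str) -> tuple[float, int, int, int]:
    """Best placement of ``query`` inside ``target`` (unit edit costs).

    Returns ``(percent_identity, target_start, target_end, aln_columns)``
    where identity = matches / alignment columns of the optimal semi-global
    alignment. Strand-naive: the caller aligns the reverse complement
    separately if needed.
    """
    if not query or not target:
        raise ValueError("infix_identity requires nonempty sequences")
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    matches = sum(1 for x, y in zip(qa, ta) if x == y and x != "-" and x != "N")
    start, end = res["locations"][0]
    return 100.0 * matches / len(qa), start, end + 1, len(qa)


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    bit_like_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")


def best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    top_k: int = 1,
    exclude_self: bool = False,
    alphabet: str = "aa",
) -> list[Hit]:
    """Per query, the ``top_k`` subjects by global percent identity.

    Ties broken by subject_id lexicographic order; self-pairs (same id)
    excluded when flagged. Deterministic for fixed input.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not subjects:
        warnings.warn("best_hits: empty subject set")
        return []
    hits: list[Hit] = []
    for qid in sorted(queries):
        qseq = queries[qid]
        scored = []
        for sid in sorted(subjects):
            if exclude_self and sid == qid:
                continue
            sseq = subjects[sid]
            ident = global_identity(qseq, sseq, alphabet)
            aln_len = max(len(qseq), len(sseq))  # lower bound on columns
            scored.append(Hit(qid, sid, ident, aln_len, ident * aln_len / 100.0))
        scored.sort(key=lambda h: (-h.percent_identity, h.subject_id))
        hits.extend(scored[:top_k])
    return hits


# ---------------------------------------------------------------------------
# external tabular search adapter (12-column blast-like format)

TABULAR_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bit_score",
]


def read_tabular_hits(path: str | Path) -> list[Hit]:
    """Ingest external search results (blast ``-outfmt 6`` layout)."""
    hits = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            hits.append(
                Hit(
                    query_id=row[0],
                    subject_id=row[1],
                    percent_identity=float(row[2]),
                    aln_length=int(row[3]),
                    bit_like_score=float(row[11]),
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                 h.aln_length, 0, 0, 0, 0, 0, 0, 0.0, f"{h.bit_like_score:.1f}"]
            )


def identity_matrix(
    seqs: Sequence[str], alphabet: str = "aa"
) -> "list[list[float]]":
    """Dense all-pairs identity (symmetric, 100 on the diagonal)."""
    n = len(seqs)
    m = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            v = global_identity(seqs[i], seqs[j], alphabet)
            m[i][j] = m[j][i] = v
    return m
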