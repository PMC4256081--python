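"""Block-based calling of indels, duplications and rearrangements.

Each cluster is cut into consecutive 1-kb blocks (trailing remainder
discarded). Every block is then placed at its most homologous location in
the partner cluster — and in its own cluster, to test for duplications — by
semi-global alignment on both strands. A pair is comparable when at least
three blocks match above the identity floor (default >70%). Event calls are
read off the matched-block index sequence:

* rearrangement — a maximal contiguous run of matched blocks participating
  in an order descent (one call per disordered segment);
* indel — a maximal run of unmatched blocks in exactly one cluster, flanked
  on both sides by >=2 matched blocks (>=2 kb) in conserved order;
* duplication — block(s) matching a partner block already claimed by an
  earlier block, with the within-cluster copy more similar than the
  cross-cluster one (higher copy number on one side).

Precedence duplication -> indel -> rearrangement: blocks consumed by a
duplication call are excluded from the order/indel analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .align import infix_identity, reverse_complement
from .model import Corpus, GeneCluster

BLOCK_SIZE = 1000
MIN_IDENTITY = 70.0
MIN_MATCHED_BLOCKS = 3
FLANK_BLOCKS = 2

IDENTITY_BINS = list(range(70, 101, 5))
SIZE_CLASSES = [(1, 10), (11, 20), (21, 30), (31, 40), (41, 10**9)]
SIZE_CLASS_LABELS = ["1-10 kb", "11-20 kb", "21-30 kb", "31-40 kb", "40+ kb"]


@dataclass(frozen=True)
class Block:
    cluster_id: str
    index: int
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class BlockMatch:
    """Best placement of one block in a partner (or its own) sequence."""

    target_index: int
    identity: float
    strand: int
    target_mid: int


@dataclass
class BlockMap:
    pair: tuple[str, str]
    a_blocks: list[Block]
    b_blocks: list[Block]
    a_matches: list[Optional[BlockMatch]]
    b_matches: list[Optional[BlockMatch]]
    a_self: list[Optional[BlockMatch]]
    b_self: list[Optional[BlockMatch]]
    min_identity: float = MIN_IDENTITY

    @property
    def n_matched(self) -> int:
        return sum(m is not None for m in self.a_matches)

    @property
    def comparable(self) -> bool:
        return self.n_matched >= MIN_MATCHED_BLOCKS

    @property
    def mean_identity(self) -> float:
        vals = [m.identity for m in self.a_matches if m is not None]
        vals += [m.identity for m in self.b_matches if m is not None]
        return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class EventCall:
    type: str  # rearrangement | indel | duplication
    pair: tuple[str, str]
    a_blocks: tuple[int, ...]
    b_blocks: tuple[int, ...]
    size_kb: float
    mean_pair_identity: float


def decompose_blocks(
    cluster: GeneCluster, block_size: int = BLOCK_SIZE
) -> list[Block]:
    """floor(L / block_size) full blocks; the trailing remainder is dropped."""
    seq = cluster.sequence
    if seq is None:
        raise ValueError(f"cluster {cluster.cluster_id!r} has no sequence")
    n = len(seq) // block_size
    if n == 0:
        warnings.warn(
            f"cluster {cluster.cluster_id!r} shorter than one block "
            f"({len(seq)} < {block_size})"
        )
    return [
        Block(cluster.cluster_id, i, i * block_size, (i + 1) * block_size,
              seq[i * block_size : (i + 1) * block_size])
        for i in range(n)
    ]


def _best_placement(
    query: str, target: str, offset: int = 0
) -> Optional[tuple[float, int, int]]:
    """(identity, midpoint, strand) of the best infix placement of ``query``
    in ``target`` over both strands; None if target too short."""
    if len(target) < len(query) // 2:
        return None
    best = None
    for strand, q in ((1, query), (-1, reverse_complement(query))):
        ident, s, e, _cols = infix_identity(q, target)
        cand = (ident, offset + (s + e) // 2, strand)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def _match_one_side(
    blocks: list[Block], target_seq: str, n_target_blocks: int,
    min_identity: float, block_size: int,
) -> list[Optional[BlockMatch]]:
    out: list[Optional[BlockMatch]] = []
    for blk in blocks:
        placed = _best_placement(blk.sequence, target_seq)
        if placed is None or placed[0] <= min_identity:
            out.append(None)
            continue
        ident, mid, strand = placed
        idx = min(mid // block_size, n_target_blocks - 1)
        out.append(BlockMatch(idx, ident, strand, mid))
    return out


def _self_matches(
    blocks: list[Block], seq: str, min_identity: float, block_size: int
) -> list[Optional[BlockMatch]]:
    """Best hit of each block elsewhere in its own cluster (own span
    excluded)."""
    n = len(blocks)
    out: list[Optional[BlockMatch]] = []
    for blk in blocks:
        cands = []
        left, right = seq[: blk.start], seq[blk.end :]
        p = _best_placement(blk.sequence, left)
        if p is not None:
            cands.append(p)
        p = _best_placement(blk.sequence, right, offset=blk.end)
        if p is not None:
            cands.append(p)
        cands = [c for c in cands if c[0] > min_identity]
        if not cands:
            out.append(None)
            continue
        ident, mid, strand = max(cands, key=lambda c: c[0])
        out.append(BlockMatch(min(mid // block_size, n - 1), ident, strand, mid))
    return out


def match_blocks(
    a: GeneCluster, b: GeneCluster, min_identity: float = MIN_IDENTITY,
    block_size: int = BLOCK_SIZE,
) -> BlockMap:
    """Place every block of ``a`` in ``b`` (and vice versa) and in its own
    cluster; matches kept only above ``min_identity``."""
    a_blocks = decompose_blocks(a, block_size)
    b_blocks = decompose_blocks(b, block_size)
    if not a_blocks or not b_blocks:
        return BlockMap((a.cluster_id, b.cluster_id), a_blocks, b_blocks,
                        [None] * len(a_blocks), [None] * len(b_blocks),
                        [None] * len(a_blocks), [None] * len(b_blocks),
                        min_identity)
    return BlockMap(
        pair=(a.cluster_id, b.cluster_id),
        a_blocks=a_blocks,
        b_blocks=b_blocks,
        a_matches=_match_one_side(a_blocks, b.sequence, len(b_blocks),
                                  min_identity, block_size),
        b_matches=_match_one_side(b_blocks, a.sequence, len(a_blocks),
                                  min_identity, block_size),
        a_self=_self_matches(a_blocks, a.sequence, min_identity, block_size),
        b_self=_self_matches(b_blocks, b.sequence, min_identity, block_size),
        min_identity=min_identity,
    )


# ---------------------------------------------------------------------------
# event calling


def _duplication_runs(
    matches: list[Optional[BlockMatch]],
    selfs: list[Optional[BlockMatch]],
) -> list[list[int]]:
    """Indices of 'extra copy' blocks: matched to a partner block already
    claimed by an earlier block, with the within-cluster hit at least as
    similar as the cross hit. Returned as maximal contiguous runs."""
    claimed: dict[int, int] = {}
    extra: list[int] = []
    for i, m in enumerate(matches):
        if m is None:
            continue
        if m.target_index in claimed:
            s = selfs[i]
            if s is not None and s.identity > m.identity:
                extra.append(i)
        else:
            claimed[m.target_index] = i
    runs: list[list[int]] = []
    for i in extra:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def _indel_runs(
    matches: list[Optional[BlockMatch]], consumed: set[int]
) -> list[list[int]]:
    """Maximal unmatched runs flanked by >=FLANK_BLOCKS matched blocks in
    conserved (ascending) order on both sides."""
    idx = [i for i in range(len(matches)) if i not in consumed]
    status = [(i, matches[i]) for i in idx]
    runs: list[list[int]] = []
    cur: list[int] = []
    for i, m in status:
        if m is None:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
                cur = []
    # a trailing unmatched run has no right flank and is never reported
    out = []
    pos_of = {i: k for k, (i, _m) in enumerate(status)}
    for run in runs:
        k0 = pos_of[run[0]]
        left = [m for (_i, m) in status[:k0] if m is not None][-FLANK_BLOCKS:]
        kn = pos_of[run[-1]]
        right = [m for (_i, m) in status[kn + 1 :] if m is not None][:FLANK_BLOCKS]
        if len(left) < FLANK_BLOCKS or len(right) < FLANK_BLOCKS:
            continue
        # conserved order = non-decreasing targets; blocks straddling the
        # indel breakpoint may share a target with a flank block
        targets = [m.target_index for m in left + right]
        if targets == sorted(targets):
            out.append(run)
    return out


def _disordered_segments(seq: list[tuple[int, int]]) -> list[list[int]]:
    """Maximal contiguous runs of positions participating in an order
    descent of the matched target-index sequence. ``seq`` holds
    (block_index, target_index) for matched blocks in cluster order."""
    n = len(seq)
    bad = [False] * n
    for k in range(n - 1):
        if seq[k + 1][1] < seq[k][1]:
            bad[k] = bad[k + 1] = True
    segments: list[list[int]] = []
    last_pos: Optional[int] = None
    for k in range(n):
        if not bad[k]:
            continue
        if last_pos == k - 1 and segments:
            segments[-1].append(seq[k][0])
        else:
            segments.append([seq[k][0]])
        last_pos = k
    return segments


def call_events(bmap: BlockMap, block_size: int = BLOCK_SIZE) -> list[EventCall]:
    """Deterministic event calls for one comparable pair."""
    if not bmap.comparable:
        return []
    calls: list[EventCall] = []
    mean_id = bmap.mean_identity
    kb = block_size / 1000.0

    a_dup_runs = _duplication_runs(bmap.a_matches, bmap.a_self)
    b_dup_runs = _duplication_runs(bmap.b_matches, bmap.b_self)
    consumed_a = {i for run in a_dup_runs for i in run}
    consumed_b = {i for run in b_dup_runs for i in run}
    for run in a_dup_runs:
        targets = tuple(sorted({bmap.a_matches[i].target_index for i in run}))
        calls.append(EventCall("duplication", bmap.pair, tuple(run), targets,
                               len(run) * kb, mean_id))
    for run in b_dup_runs:
        targets = tuple(sorted({bmap.b_matches[i].target_index for i in run}))
        calls.append(EventCall("duplication", bmap.pair, targets, tuple(run),
                               len(run) * kb, mean_id))

    # blocks immediately flanking a duplication run sit on the copy
    # breakpoint and are ambiguous; keep them out of indel runs
    indel_excl_a = consumed_a | {i - 1 for i in consumed_a} | {i + 1 for i in consumed_a}
    indel_excl_b = consumed_b | {i - 1 for i in consumed_b} | {i + 1 for i in consumed_b}
    for run in _indel_runs(bmap.a_matches, indel_excl_a):
        calls.append(EventCall("indel", bmap.pair, tuple(run), (),
                               len(run) * kb, mean_id))
    for run in _indel_runs(bmap.b_matches, indel_excl_b):
        calls.append(EventCall("indel", bmap.pair, (), tuple(run),
                               len(run) * kb, mean_id))

    matched_seq = [
        (i, bmap.a_matches[i].target_index)
        for i in range(len(bmap.a_blocks))
        if i not in consumed_a and bmap.a_matches[i] is not None
    ]
    for seg in _disordered_segments(matched_seq):
        targets = tuple(sorted(bmap.a_matches[i].target_index for i in seg))
        calls.append(EventCall("rearrangement", bmap.pair, tuple(seg),
                               targets, len(seg) * kb, mean_id))
    return calls


# ---------------------------------------------------------------------------
# corpus-level summary


@dataclass
class EventSummary:
    counts_by_identity: pd.DataFrame
    counts_by_size_class: pd.DataFrame
    indel_size_hist: pd.DataFrame
    n_pairs: int = 0
    n_comparable: int = 0

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts_by_identity.to_csv(out / "events_by_identity.tsv",
                                       sep="\t")
        self.counts_by_size_class.to_csv(out / "events_by_size_class.tsv",
                                         sep="\t")
        self.indel_size_hist.to_csv(out / "indel_sizes.tsv", sep="\t")


def _size_class(length_bp: int) -> str:
    kb = length_bp / 1000.0
    for (lo, hi), label in zip(SIZE_CLASSES, SIZE_CLASS_LABELS):
        if lo <= kb <= hi:
            return label
    return SIZE_CLASS_LABELS[0]


def summarize_events(
    corpus: Corpus, maps: list[BlockMap], calls: list[EventCall]
) -> EventSummary:
    """Per-type counts binned by pair mean identity (5% bins) and by cluster
    size class, plus the indel size histogram in kb."""
    types = ["rearrangement", "indel", "duplication"]
    id_bins = [f"{lo}-{lo + 5}%" for lo in IDENTITY_BINS[:-1]]
    by_ident = pd.DataFrame(0, index=id_bins, columns=types)
    by_size = pd.DataFrame(0, index=SIZE_CLASS_LABELS, columns=types)
    lengths = {c.cluster_id: c.length for c in corpus}
    for call in calls:
        lo = min(int(call.mean_pair_identity // 5) * 5, 95)
        if lo >= IDENTITY_BINS[0]:
            by_ident.loc[f"{lo}-{lo + 5}%", call.type] += 1
        size = max(lengths.get(call.pair[0], 0), lengths.get(call.pair[1], 0))
        by_size.loc[_size_class(size), call.type] += 1
    indel_sizes = sorted(c.size_kb for c in calls if c.type == "indel")
    max_kb = int(max(indel_sizes)) if indel_sizes else 1
    hist_index = list(range(1, max(10, max_kb) + 1))
    hist = pd.DataFrame(0, index=hist_index, columns=["count"])
    for s in indel_sizes:
        hist.loc[min(int(round(s)), hist_index[-1]), "count"] += 1
    return EventSummary(by_ident, by_size, hist,
                        n_pairs=len(maps),
                        n_comparable=sum(m.comparable for m in maps))


def events_to_bed(calls: list[EventCall], block_size: int = BLOCK_SIZE) -> str:
    """BED lines for the A-side spans of each call."""
    lines = []
    for c in calls:
        blocks = c.a_blocks or c.b_blocks
        cid = c.pair[0] if c.a_blocks else c.pair[1]
        if not blocks:
            continue
        lines.append(
            f"{cid}\t{min(blocks) * block_size}\t{(max(blocks) + 1) * block_size}"
            f"\t{c.type}\t{c.size_kb:g}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def call_corpus_events(
    corpus: Corpus, min_identity: float = MIN_IDENTITY,
    block_size: int = BLOCK_SIZE,
) -> tuple[list[BlockMap], list[EventCall]]:
    """All-vs-all block maps and event calls over a corpus."""
    maps, calls = [], []
    for i in range(len(corpus)):
        for j in range(i + 1, len(corpus)):
            bmap = match_blocks(corpus[i], corpus[j], min_identity, block_size)
            maps.append(bmap)
            calls.extend(call_events(bmap, block_size))
    return maps, calls
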