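"""Anchored pairwise alignment of consensus sequences onto long reads.

The mapper follows the classic seed-chain-align recipe: exact k-mer anchors
shared between a consensus and a read are chained along diagonals, each chain
is turned into a candidate placement, and edlib's banded bit-parallel
alignment scores the spanned segments. This stands behind both rDNA gene
detection and repeat-library annotation; any mapper meeting the recall and
composition-recovery properties is interchangeable here.

edlib extended CIGARs use ``=``/``X`` for match/mismatch, ``I`` for a base
present only in the query and ``D`` for a base present only in the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .core import SequenceRecord, reverse_complement

__all__ = [
    "Placement",
    "kmer_index",
    "find_anchors",
    "chain_anchors",
    "locate",
    "locate_both_strands",
    "global_identity",
    "cigar_walk",
]

# chaining tolerances: successive anchors may drift this many diagonals
# (absorbs indels) and skip this many read bases (absorbs anchor dropouts)
_MAX_DIAG_DRIFT = 50
_MAX_ANCHOR_SKIP = 600


@dataclass
class Placement:
    """One placement of a consensus segment on a read (plus-strand coords)."""

    q_start: int  # on the read
    q_end: int
    s_start: int  # on the consensus
    s_end: int
    strand: str
    n_anchors: int
    identity: float  # matches / alignment columns
    matches: int  # alignment score proxy

    def q_len(self) -> int:
        return self.q_end - self.q_start


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer in ``seq``; k-mers containing N are skipped."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def find_anchors(
    subject: str, read_index: dict[str, list[int]], k: int
) -> list[tuple[int, int]]:
    """Exact shared k-mers as (read_pos, subject_pos) pairs."""
    anchors = []
    for j in range(len(subject) - k + 1):
        kmer = subject[j : j + k]
        if "N" in kmer:
            continue
        for i in read_index.get(kmer, ()):
            anchors.append((i, j))
    return anchors


def chain_anchors(anchors: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Greedy co-linear chaining of anchors along near-constant diagonals.

    Anchors are swept in read order; each joins the best-matching open chain
    whose last anchor is upstream on both sequences and on a nearby diagonal,
    else founds a new chain. Tandem copies of a subject therefore come out as
    separate chains (one per copy), which downstream merging may collapse.
    """
    chains: list[list[tuple[int, int]]] = []
    active: list[int] = []  # indices of chains whose tail is still reachable
    tails: dict[int, tuple[int, int]] = {}
    for i, j in sorted(anchors):
        diag = i - j
        # retire chains that fell behind the sweep line
        active = [c for c in active if i - tails[c][0] <= _MAX_ANCHOR_SKIP]
        best = -1
        best_gap = None
        for c in active:
            ti, tj = tails[c]
            if not (ti <= i and tj < j):
                continue
            if abs(diag - (ti - tj)) > _MAX_DIAG_DRIFT:
                continue
            gap = i - ti
            if best_gap is None or gap < best_gap:
                best, best_gap = c, gap
        if best >= 0:
            chains[best].append((i, j))
            tails[best] = (i, j)
        else:
            chains.append([(i, j)])
            tails[len(chains) - 1] = (i, j)
            active.append(len(chains) - 1)
    return chains


def cigar_walk(cigar: str):
    """Yield (count, op) pairs from an edlib extended CIGAR."""
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def _segment_stats(read_seg: str, subj_seg: str) -> tuple[int, int]:
    """(matches, alignment columns) of a global alignment of two segments."""
    res = edlib.align(subj_seg, read_seg, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in cigar_walk(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def locate(
    subject: str,
    read: str,
    read_index: dict[str, list[int]],
    k: int = 15,
    min_anchors: int = 2,
    identity_floor: float = 0.75,
    strand: str = "+",
    min_span: int | None = None,
) -> list[Placement]:
    """All placements of ``subject`` (or a part of it) on ``read``.

    Chains with fewer than ``min_anchors`` anchors, spanning less than
    ``min_span`` read bases (default 2k, suppressing chance micro-matches),
    or below the identity floor are dropped; partial (truncated) subject
    copies are reported with the covered subject interval.
    """
    if min_span is None:
        min_span = 2 * k
    placements = []
    for chain in chain_anchors(find_anchors(subject, read_index, k)):
        if len(chain) < min_anchors:
            continue
        q_start = min(i for i, _ in chain)
        q_end = max(i for i, _ in chain) + k
        if q_end - q_start < min_span:
            continue
        s_start = min(j for _, j in chain)
        s_end = max(j for _, j in chain) + k
        matches, columns = _segment_stats(
            read[q_start:q_end], subject[s_start:s_end]
        )
        identity = matches / columns if columns else 0.0
        if identity < identity_floor:
            continue
        placements.append(
            Placement(
                q_start, q_end, s_start, s_end, strand, len(chain), identity, matches
            )
        )
    return placements


def locate_both_strands(
    subject: str,
    read: str,
    read_index: dict[str, list[int]],
    k: int = 15,
    min_anchors: int = 2,
    identity_floor: float = 0.75,
) -> list[Placement]:
    """Placements of the subject on either strand, in read plus-strand coords.

    Minus-strand placements carry subject coordinates on the subject's own
    plus strand (i.e. the interval of the consensus that is present).
    """
    hits = locate(subject, read, read_index, k, min_anchors, identity_floor, "+")
    rc = reverse_complement(subject)
    for p in locate(rc, read, read_index, k, min_anchors, identity_floor, "-"):
        s_len = len(subject)
        p.s_start, p.s_end = s_len - p.s_end, s_len - p.s_start
        hits.append(p)
    return hits


def global_identity(a: str, b: str) -> float:
    """CD-HIT-style identity: matching columns / length of the shorter sequence.

    N never counts as a match (edlib treats it as a distinct symbol, so an
    N-N column is excluded explicitly).
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    ai = bi = 0
    for n, op in cigar_walk(res["cigar"]):
        if op == "=":
            matches += n - sum(
                1 for t in range(n) if a[ai + t] == "N"
            )
            ai += n
            bi += n
        elif op == "X":
            ai += n
            bi += n
        elif op == "I":
            ai += n
        elif op == "D":
            bi += n
    return matches / min(len(a), len(b))
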