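"""Short-read coverage profiling over a unit consensus.

Preprocessed paired-end reads are placed on the single-unit consensus
(best placement only, seeded random tie-break among equal scores), giving a
per-position depth vector; LOESS smoothing and per-annotation-block mean
depths reproduce the study's coverage figures. Because the tandem units are
near-identical, depth on the consensus is the per-unit-copy collapse, so the
ratio of an inserted element's block mean to its host gene's block mean
estimates the fraction of units carrying the insertion.

The consensus is treated as circular by default (the unit is one period of
a tandem array), which removes edge artifacts at the unit boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .core import AnnotationBlock, PipelineConfig, SequenceRecord, reverse_complement

__all__ = [
    "CoverageProfile",
    "InsertionEstimate",
    "compute_depth",
    "loess_smooth",
    "block_means",
    "insertion_fraction",
    "genome_proportion",
]

_SEED_OFFSETS = 3  # probe k-mers per read for candidate placements


@dataclass
class CoverageProfile:
    consensus_id: str
    depth: np.ndarray
    smoothed: np.ndarray
    block_means: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass
class InsertionEstimate:
    element: str
    host: str
    fraction: float
    note: str = ""


def _align_read(
    read_seq: str,
    consensus: str,
    ext: str,
    index: dict[str, list[int]],
    k: int,
    min_identity: float,
) -> list[tuple[int, int, int]]:
    """Best placements of one read orientation: (score, start, aligned_len)."""
    L = len(read_seq)
    if L < k:
        return []
    offsets = sorted({0, L // 2, L - k})
    candidates: set[int] = set()
    for off in offsets[:_SEED_OFFSETS]:
        kmer = read_seq[off : off + k]
        for pos in index.get(kmer, ()):
            candidates.add(pos - off)
    placements = []
    pad = max(4, L // 10)
    for cand in candidates:
        lo = max(0, cand - pad)
        hi = min(len(ext), cand + L + pad)
        if hi - lo < L:
            continue
        res = edlib.align(read_seq, ext[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0 or 1 - dist / L < min_identity:
            continue
        t0, t1 = res["locations"][0]
        placements.append((L - dist, lo + t0, t1 - t0 + 1))
    if not placements:
        return []
    best = max(p[0] for p in placements)
    # unique placements (same start may arise from several seeds)
    return sorted({p for p in placements if p[0] == best})


def compute_depth(
    short_reads: list[SequenceRecord],
    consensus: SequenceRecord,
    config: PipelineConfig,
    circular: bool = True,
    min_identity: float = 0.90,
    seed: int = 0,
    k: int = 15,
    return_alignments: bool = False,
):
    """Per-position read depth over the consensus.

    Each read (either orientation) is seeded by exact k-mers, candidate
    placements are scored by edlib, the best placement wins and ties are
    broken by a seeded RNG; placements under ``min_identity`` are discarded.
    With ``circular`` the consensus is a ring: reads may wrap the boundary
    and depth is accumulated modulo the unit length.
    """
    n = len(consensus.residues)
    max_read = max((len(r) for r in short_reads), default=0)
    if short_reads and n < max_read:
        raise ValueError(f"consensus ({n} bp) shorter than reads ({max_read} bp)")
    rng = np.random.default_rng(seed)
    ext = consensus.residues + (consensus.residues[: max_read + 16] if circular else "")
    index: dict[str, list[int]] = {}
    limit = n if circular else n - k + 1
    for i in range(limit):
        index.setdefault(ext[i : i + k], []).append(i)

    depth = np.zeros(n, dtype=np.int64)
    alignments = []
    for read in short_reads:
        cands = []
        for strand, seq in (("+", read.residues), ("-", reverse_complement(read.residues))):
            for score, start, alen in _align_read(seq, consensus.residues, ext, index, k, min_identity):
                cands.append((score, strand, start, alen))
        if not cands:
            continue
        best = max(c[0] for c in cands)
        ties = [c for c in cands if c[0] == best]
        _, strand, start, alen = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
        idx = np.arange(start, start + alen)
        if circular:
            idx %= n
        else:
            idx = idx[idx < n]
        depth[idx] += 1
        if return_alignments:
            alignments.append((read.id, strand, start, alen))
    if return_alignments:
        return depth, alignments
    return depth


def loess_smooth(depth: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted linear regression (tricube weights) at every position.

    The window holds ``round(span * n)`` nearest positions (shifted inward
    at the edges so the window size is constant). Constants and straight
    lines are reproduced exactly; output is clamped at zero since depth
    cannot be negative.
    """
    if not (0 < span <= 1):
        raise ValueError("span outside (0, 1]")
    y = np.asarray(depth, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 positions to smooth")
    w = max(3, int(round(span * n)))
    w = min(w, n)
    half = w // 2
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        left = min(max(0, i - half), n - w)
        xs = x[left : left + w]
        ys = y[left : left + w]
        d = np.abs(xs - i)
        dmax = d.max()
        if dmax == 0:
            out[i] = ys.mean()
            continue
        tw = (1 - (d / dmax) ** 3) ** 3
        tw = np.clip(tw, 0, None)
        sw = tw.sum()
        xm = (tw * xs).sum() / sw
        ym = (tw * ys).sum() / sw
        sxx = (tw * (xs - xm) ** 2).sum()
        if sxx < 1e-12:
            out[i] = ym
        else:
            beta = (tw * (xs - xm) * (ys - ym)).sum() / sxx
            out[i] = ym + beta * (i - xm)
    return np.clip(out, 0.0, None)


def block_means(depth: np.ndarray, blocks: list[AnnotationBlock]) -> dict[str, float]:
    """Arithmetic mean of raw depth per annotation label.

    A label occurring in several blocks (e.g. a 28S split by an insertion)
    is averaged over the union of its positions.
    """
    n = len(depth)
    pos: dict[str, list[np.ndarray]] = {}
    for b in blocks:
        if b.end <= b.start:
            raise ValueError(f"zero-length block {b.label}")
        if b.end > n or b.start < 0:
            raise ValueError(f"block {b.label} outside consensus bounds")
        pos.setdefault(b.label, []).append(np.arange(b.start, b.end))
    return {
        label: float(np.asarray(depth)[np.unique(np.concatenate(parts))].mean())
        for label, parts in pos.items()
    }


def insertion_fraction(
    profile: CoverageProfile, element: str, host: str
) -> InsertionEstimate:
    """Fraction of host-gene copies carrying the element, from block means.

    Valid when the element occurs only inside the locus; an element also
    present elsewhere in the genome makes this ratio an overestimate of the
    per-unit fraction (as for a satellite shared with non-rDNA loci).
    """
    means = profile.block_means
    for label in (element, host):
        if label not in means:
            raise ValueError(f"no block mean for {label!r}")
    if means[host] <= 0:
        raise ValueError(f"host {host!r} has zero mean coverage")
    note = (
        "ratio of element to host block mean; overestimates the per-unit "
        "fraction if the element also occurs outside the rDNA locus"
    )
    return InsertionEstimate(element, host, means[element] / means[host], note)


def genome_proportion(
    short_reads: list[SequenceRecord],
    rdna_consensus: SequenceRecord,
    config: PipelineConfig,
    circular: bool = True,
    min_identity: float = 0.90,
    seed: int = 0,
) -> float:
    """Fraction of read bp that aligns to the rDNA unit consensus.

    A read-mapping analogue of graph-clustering genome-proportion
    estimates: with uniformly drawn reads it recovers the fraction of the
    genome occupied by the rDNA locus.
    """
    total_bp = sum(len(r) for r in short_reads)
    if total_bp == 0:
        raise ValueError("no read bp supplied")
    _, alignments = compute_depth(
        short_reads,
        rdna_consensus,
        config,
        circular=circular,
        min_identity=min_identity,
        seed=seed,
        return_alignments=True,
    )
    aligned_bp = sum(alen for _, _, _, alen in alignments)
    return aligned_bp / total_bp
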