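"""Long-read filtering and rDNA-bearing read identification.

Mirrors the study's mining protocol: keep reads of at least 15 kb whose mean
quality exceeds Q10, then call a read rDNA-bearing when local alignments of
the rDNA transcription-unit references (18S, ITS1, 5.8S, ITS2, 28S) cover at
least 1,000 bp of it. Short paired-end reads are preprocessed by the same
rules the study applied before repeat quantification: mean quality strictly
over Q18 and 3'-trimming to a uniform 120 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import align
from .core import Interval, PipelineConfig, SequenceRecord, merge_intervals

__all__ = [
    "ReadFilterResult",
    "RdnaCall",
    "mean_read_quality",
    "filter_reads",
    "detect_rdna",
    "preprocess_short_reads",
]

log = logging.getLogger(__name__)


@dataclass
class ReadFilterResult:
    read_id: str
    length: int
    mean_q: float
    passed: bool


@dataclass
class RdnaCall:
    read_id: str
    hits: list[tuple[str, align.Placement]] = field(default_factory=list)
    rdna_bp: int = 0
    is_rdna: bool = False


def mean_read_quality(qualities: list[int]) -> float:
    """Read-level Phred quality: the per-base error probabilities are
    averaged and converted back to the Phred scale,
    ``Q = -10*log10(mean_i 10^(-q_i/10))``.

    This is the convention of the long-read filtering tools the community
    uses; an arithmetic mean of Phred scores would overstate quality.
    """
    if not qualities:
        raise ValueError("cannot compute mean quality of an empty read")
    mean_p = sum(10 ** (-q / 10) for q in qualities) / len(qualities)
    return -10 * math.log10(mean_p)


def filter_reads(
    reads: list[SequenceRecord], config: PipelineConfig
) -> list[ReadFilterResult]:
    """Length >= min_read_length and mean quality strictly > min_mean_q."""
    results = []
    for read in reads:
        if read.qualities is None:
            log.warning("read %s lacks qualities; failed", read.id)
            results.append(ReadFilterResult(read.id, len(read), float("nan"), False))
            continue
        q = mean_read_quality(read.qualities)
        # strict >, robust to float error in the Phred back-transform
        passed = len(read) >= config.min_read_length and q > config.min_mean_q + 1e-9
        results.append(ReadFilterResult(read.id, len(read), q, passed))
    return results


def detect_rdna(
    read: SequenceRecord,
    gene_refs: dict[str, str],
    config: PipelineConfig,
) -> RdnaCall:
    """Local-alignment search of the unit references on both strands.

    The cumulative rDNA content of the read is the union of all gene-hit
    intervals on the read (small gaps up to ``rdna_union_gap`` — single
    substitutions fragmenting exact anchors — are bridged); the read is
    rDNA-bearing when that union reaches ``min_rdna_bp``.
    """
    if not gene_refs:
        raise ValueError("empty gene reference set")
    call = RdnaCall(read.id)
    index = align.kmer_index(read.residues, config.anchor_k)
    intervals: list[Interval] = []
    for label, ref in gene_refs.items():
        for hit in align.locate_both_strands(
            ref,
            read.residues,
            index,
            k=config.anchor_k,
            min_anchors=config.min_anchors,
            identity_floor=config.identity_floor,
        ):
            call.hits.append((label, hit))
            intervals.append(Interval(read.id, hit.q_start, hit.q_end))
    call.rdna_bp = sum(
        len(iv) for iv in merge_intervals(intervals, max_gap=config.rdna_union_gap)
    )
    call.is_rdna = call.rdna_bp >= config.min_rdna_bp
    return call


def preprocess_short_reads(
    mates1: list[SequenceRecord],
    mates2: list[SequenceRecord],
    config: PipelineConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Quality-filter and 3'-trim paired short reads.

    A pair survives only if both mates have mean quality strictly above
    ``short_read_min_q``; survivors are trimmed from the 3' end to the
    uniform ``short_read_trim_len`` (reads already shorter are dropped with
    their mate, so all surviving reads share one length).
    """
    if len(mates1) != len(mates2):
        raise ValueError(
            f"mismatched mate files: {len(mates1)} vs {len(mates2)} reads"
        )
    out1, out2 = [], []
    trim = config.short_read_trim_len
    for r1, r2 in zip(mates1, mates2):
        ok = True
        for r in (r1, r2):
            if r.qualities is None or len(r) < trim:
                ok = False
                break
            if mean_read_quality(r.qualities) <= config.short_read_min_q + 1e-9:
                ok = False
                break
        if not ok:
            continue
        out1.append(SequenceRecord(r1.id, r1.residues[:trim], r1.qualities[:trim]))
        out2.append(SequenceRecord(r2.id, r2.residues[:trim], r2.qualities[:trim]))
    return out1, out2
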