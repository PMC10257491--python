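"""Tandem-repeat (satellite) detection and array geometry.

Satellite arrays are found by self-comparison periodicity — the in-silico
counterpart of reading a self-dotplot: repeated k-mers within a sequence
vote with the spacing between their consecutive occurrences, and a run of
positions dominated by one spacing is a tandem array with that monomer
length. Array lengths feed the per-species length statistics (median, max,
quartiles) and the count of satellite-only reads (satellite present,
no rDNA, no IGS element).
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass

from .align import global_identity
from .core import AnnotationBlock, Interval, PipelineConfig, reverse_complement

__all__ = [
    "SatelliteArray",
    "ArrayLengthStats",
    "detect_tandem_arrays",
    "array_length_stats",
    "detect_microsatellite",
]


@dataclass
class SatelliteArray:
    read_id: str
    interval: Interval
    monomer_len: int
    n_copies: float

    @property
    def array_len(self) -> int:
        return len(self.interval)


@dataclass
class ArrayLengthStats:
    n_arrays: int
    median: float | None
    maximum: int | None
    q1: float | None
    q3: float | None
    n_satellite_only_reads: int


def detect_tandem_arrays(
    seq: str,
    min_period: int = 10,
    max_period: int = 2000,
    k: int = 12,
    min_support: int = 5,
    adjacent_identity_floor: float = 0.70,
    seq_id: str = "seq",
) -> list[SatelliteArray]:
    """Detect maximal tandem arrays and estimate their monomer length.

    Each repeated k-mer contributes (position, spacing) events for the
    spacings between its consecutive occurrences within [min_period,
    max_period]. Events are grouped into runs along the sequence; a run's
    period is the modal spacing refined by the median of spacings within
    20% of the mode, and its boundaries are the extent of the supporting
    k-mers plus one period on the right. Runs failing an adjacent-monomer
    identity check or spanning under ~2 copies are dropped; arrays
    overlapping by more than half are deduplicated keeping the higher copy
    number.
    """
    if len(seq) < 2 * min_period:
        return []
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    events: list[tuple[int, int]] = []  # (position, spacing)
    for occ in positions.values():
        if len(occ) < 2:
            continue
        for a, b in zip(occ, occ[1:]):
            d = b - a
            if min_period <= d <= max_period:
                events.append((a, d))
    if not events:
        return []
    events.sort()

    # group events into runs: a gap larger than twice the running modal
    # spacing (or the spacing itself for sparse support) breaks the run
    runs: list[list[tuple[int, int]]] = [[events[0]]]
    counter = Counter([events[0][1]])
    mode_d, mode_n = events[0][1], 1
    for ev in events[1:]:
        run = runs[-1]
        if ev[0] - run[-1][0] <= max(2 * mode_d, 2 * k):
            run.append(ev)
            counter[ev[1]] += 1
            if counter[ev[1]] > mode_n:
                mode_d, mode_n = ev[1], counter[ev[1]]
        else:
            runs.append([ev])
            counter = Counter([ev[1]])
            mode_d, mode_n = ev[1], 1

    arrays: list[SatelliteArray] = []
    for run in runs:
        if len(run) < min_support:
            continue
        mode_d = Counter(d for _, d in run).most_common(1)[0][0]
        band = [d for _, d in run if abs(d - mode_d) <= 0.2 * mode_d]
        period = int(round(statistics.median(band)))
        support = [(p, d) for p, d in run if abs(d - mode_d) <= 0.2 * mode_d]
        start = min(p for p, _ in support)
        end = max(p + d + k for p, d in support)
        end = min(end, len(seq))
        if end - start < 1.8 * period or period < min_period:
            continue
        a = seq[start : start + period]
        b = seq[start + period : start + 2 * period]
        if len(b) == len(a) and global_identity(a, b) < adjacent_identity_floor:
            continue
        arrays.append(
            SatelliteArray(
                seq_id,
                Interval(seq_id, start, end),
                period,
                round((end - start) / period, 2),
            )
        )

    # deduplicate arrays overlapping >50% (keep higher copy number)
    arrays.sort(key=lambda s: (-s.n_copies, s.interval.start))
    kept: list[SatelliteArray] = []
    for arr in arrays:
        redundant = any(
            arr.interval.overlap(other.interval) > 0.5 * len(arr.interval)
            for other in kept
        )
        if not redundant:
            kept.append(arr)
    kept.sort(key=lambda s: s.interval.start)
    return kept


def array_length_stats(
    arrays: list[SatelliteArray],
    annotations: list,
    is_rdna: dict[str, bool],
    config: PipelineConfig,
) -> ArrayLengthStats:
    """Length statistics over satellite arrays plus satellite-only reads.

    A satellite-only read carries at least ``min_satellite_bp`` of the
    satellite, no rDNA call, and no IGS mobile-element hit. Statistics on an
    empty array set are reported as absent (None), not zero.
    """
    from .annotate import _element_labels  # local import avoids a cycle

    lengths = sorted(a.array_len for a in arrays)
    if lengths:
        med = statistics.median(lengths)
        q = statistics.quantiles(lengths, n=4) if len(lengths) > 1 else [None] * 3
        stats = (med, lengths[-1], q[0], q[2])
    else:
        stats = (None, None, None, None)

    n_only = 0
    for ann in annotations:
        if ann.satellite_bp < config.min_satellite_bp:
            continue
        if is_rdna.get(ann.read_id, False):
            continue
        if _element_labels(ann.element_bp):
            continue
        n_only += 1
    return ArrayLengthStats(len(lengths), *stats, n_only)


def detect_microsatellite(
    seq: str,
    motifs: list[str],
    seq_id: str = "seq",
    min_copies: int = 3,
    max_mismatch: float = 0.10,
) -> list[AnnotationBlock]:
    """Maximal tandem runs of short motifs on either strand.

    A run is chained from exact motif occurrences spaced by at most two
    motif lengths, must span at least ``min_copies`` copies and match the
    cyclic motif at >=90% of its positions. Runs of the same motif within
    one motif length of each other are merged. Minus-strand runs are
    reported on plus-strand coordinates with strand '-'.
    """
    blocks: list[AnnotationBlock] = []
    for motif in motifs:
        if not (2 <= len(motif) <= 10):
            raise ValueError(f"motif {motif!r} outside 2-10 bp")
        for strand, probe in (("+", motif), ("-", reverse_complement(motif))):
            for start, end in _motif_runs(seq, probe, min_copies, max_mismatch):
                blocks.append(
                    AnnotationBlock(
                        f"msat_{motif}",
                        Interval(seq_id, start, end, strand),
                        "inferred",
                    )
                )
    # merge same-label runs within one motif length
    blocks.sort(key=lambda b: (b.label, b.start))
    merged: list[AnnotationBlock] = []
    for b in blocks:
        if (
            merged
            and merged[-1].label == b.label
            and merged[-1].interval.strand == b.interval.strand
            and b.start - merged[-1].end <= len(b.label) - 5  # label = msat_ + motif
        ):
            prev = merged.pop()
            iv = Interval(
                prev.interval.ref_id,
                prev.start,
                max(prev.end, b.end),
                prev.interval.strand,
            )
            merged.append(AnnotationBlock(prev.label, iv, "inferred"))
        else:
            merged.append(b)
    merged.sort(key=lambda b: b.start)
    return merged


def _motif_runs(seq: str, motif: str, min_copies: int, max_mismatch: float):
    L = len(motif)
    occ = []
    i = seq.find(motif)
    while i != -1:
        occ.append(i)
        i = seq.find(motif, i + 1)
    if not occ:
        return
    # chain occurrences spaced by <= 2 motif lengths
    chains = [[occ[0]]]
    for p in occ[1:]:
        if p - chains[-1][-1] <= 2 * L:
            chains[-1].append(p)
        else:
            chains.append([p])
    for chain in chains:
        start, end = chain[0], chain[-1] + L
        if end - start < min_copies * L:
            continue
        matches = sum(
            1 for p in range(start, end) if seq[p] == motif[(p - start) % L]
        )
        if matches >= (1 - max_mismatch) * (end - start):
            yield start, end
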