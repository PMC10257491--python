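"""Repeat-library annotation of rDNA-bearing long reads.

Consensus sequences of the rDNA genes, IGS mobile-element fragments and
satellite monomers are mapped onto each read; placements below a uniqueness
(mapping-quality) threshold are discarded, mirroring the study's rule that
only regions with mapping quality of at least 20 are considered. The
surviving hits give each read an ordered composition string, per-element
presence, an R2-in-28S flag, and a cohort-level classification into
canonical / ME-free / irregular reads against the modal composition.

Mapping quality here is a uniqueness proxy: a placement that is the only
home of its consensus segment on the read scores 60; perfectly ambiguous
duplicate placements score 0; in between, ``mapq = min(60, round(40*(1 -
s2/s1)))`` over the best and second-best placement scores. Tandem copies of
one label lying within the merge gap are collapsed into a single placement
*before* uniqueness is assessed, so a contiguous satellite array counts as
one (unique) placement while two distant identical element copies silence
each other — the behaviour of the aligner-based protocol this replaces.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import edlib

from . import align
from .core import (
    GENE_LABELS,
    Interval,
    PipelineConfig,
    SequenceRecord,
    reverse_complement,
)

__all__ = [
    "AlignmentHit",
    "ReadAnnotation",
    "CohortSummary",
    "map_library",
    "filter_and_merge_hits",
    "compose_read",
    "classify_cohort",
    "polish_consensus",
]

log = logging.getLogger(__name__)

#: labels treated as insertions into the transcription unit (R2-type, R1-type)
INSERTION_LABELS = ("R2", "R1")

#: slop (bp) when testing whether an insertion lies inside a host gene hit:
#: with exact boundaries the insertion abuts, not overlaps, the split host
_INSERTION_SLOP = 50


@dataclass
class AlignmentHit:
    label: str
    query: Interval  # on the read, plus-strand coordinates
    subject: Interval  # on the consensus
    identity: float
    score: int  # matches
    mapq: int = 60

    def q_len(self) -> int:
        return len(self.query)


@dataclass
class ReadAnnotation:
    read_id: str
    read_len: int | None = None
    hits: list[AlignmentHit] = field(default_factory=list)
    composition: list[str] = field(default_factory=list)
    orientation: str = "+"
    element_bp: dict[str, int] = field(default_factory=dict)
    igs_composition: tuple[str, ...] | None = None  # None = no full IGS spanned
    has_r2_in_28S: bool = False
    me_free: bool = True
    satellite_bp: int = 0
    irregular: bool | None = None


def _element_labels(labels) -> set[str]:
    """Mobile-element labels: everything that is not a gene, anonymous
    spacer, satellite or microsatellite."""
    skip = set(GENE_LABELS) | {"IGS", "satellite"}
    return {l for l in labels if l not in skip and not l.startswith("msat_")}


def map_library(
    read: SequenceRecord,
    library: dict[str, str],
    config: PipelineConfig,
) -> list[AlignmentHit]:
    """Map every library consensus onto the read (both strands).

    Partial (truncated) copies are found and reported with the covered
    consensus interval. Adjacent same-label placements within ``merge_gap``
    are collapsed, then mapping quality is computed from score ties between
    placements of the same consensus elsewhere on the read.
    """
    if not library:
        raise ValueError("empty consensus library")
    index = align.kmer_index(read.residues, config.anchor_k)
    hits: list[AlignmentHit] = []
    for label, consensus in library.items():
        placements = align.locate_both_strands(
            consensus,
            read.residues,
            index,
            k=config.anchor_k,
            min_anchors=config.min_anchors,
            identity_floor=config.identity_floor,
        )
        merged = _merge_placements(placements, config.merge_gap)
        scores = [p.matches for p in merged]
        for i, p in enumerate(merged):
            s1 = p.matches
            rivals = [
                s
                for j, s in enumerate(scores)
                if j != i and _subject_overlap(merged[j], p) >= 0.5
            ]
            s2 = max(rivals, default=0)
            if s2 == 0:
                mapq = 60
            elif s2 >= s1:  # a better (or equal) home exists elsewhere
                mapq = 0
            else:
                mapq = min(60, round(40 * (1 - s2 / s1)))
            hits.append(
                AlignmentHit(
                    label,
                    Interval(read.id, p.q_start, p.q_end, p.strand),
                    Interval(label, p.s_start, p.s_end),
                    p.identity,
                    p.matches,
                    mapq,
                )
            )
    hits.sort(key=lambda h: (h.query.start, h.query.end, h.label))
    return hits


def _subject_overlap(a: align.Placement, b: align.Placement) -> float:
    """Fraction of the shorter subject span shared by two placements."""
    inter = max(0, min(a.s_end, b.s_end) - max(a.s_start, b.s_start))
    shorter = min(a.s_end - a.s_start, b.s_end - b.s_start)
    return inter / shorter if shorter else 0.0


def _merge_placements(
    placements: list[align.Placement], merge_gap: int
) -> list[align.Placement]:
    """Collapse same-strand placements within ``merge_gap`` on the read."""
    out: list[align.Placement] = []
    for p in sorted(placements, key=lambda x: (x.q_start, x.q_end)):
        if out and p.strand == out[-1].strand and p.q_start <= out[-1].q_end + merge_gap:
            prev = out[-1]
            prev.q_end = max(prev.q_end, p.q_end)
            prev.s_start = min(prev.s_start, p.s_start)
            prev.s_end = max(prev.s_end, p.s_end)
            prev.n_anchors += p.n_anchors
            total = prev.matches + p.matches
            span = prev.matches / prev.identity + p.matches / p.identity
            prev.matches = total
            prev.identity = total / span if span else 0.0
        else:
            out.append(p)
    return out


def filter_and_merge_hits(
    hits: list[AlignmentHit], config: PipelineConfig
) -> list[AlignmentHit]:
    """Drop hits below the mapping-quality threshold, then merge same-label
    neighbours within ``merge_gap`` (summed scores, length-weighted identity)."""
    kept = [h for h in hits if h.mapq >= config.min_mapq]
    kept.sort(key=lambda h: (h.label, h.query.start))
    out: list[AlignmentHit] = []
    for h in kept:
        if (
            out
            and out[-1].label == h.label
            and out[-1].query.strand == h.query.strand
            and h.query.start <= out[-1].query.end + config.merge_gap
        ):
            prev = out[-1]
            w1, w2 = prev.q_len(), h.q_len()
            prev.identity = (prev.identity * w1 + h.identity * w2) / (w1 + w2)
            prev.query = Interval(
                prev.query.ref_id,
                prev.query.start,
                max(prev.query.end, h.query.end),
                prev.query.strand,
            )
            prev.subject = Interval(
                prev.subject.ref_id,
                min(prev.subject.start, h.subject.start),
                max(prev.subject.end, h.subject.end),
            )
            prev.score += h.score
            prev.mapq = max(prev.mapq, h.mapq)
        else:
            out.append(
                AlignmentHit(
                    h.label, h.query, h.subject, h.identity, h.score, h.mapq
                )
            )
    out.sort(key=lambda h: (h.query.start, h.query.end, h.label))
    return out


def compose_read(
    hits: list[AlignmentHit],
    insertion_labels: tuple[str, ...] = INSERTION_LABELS,
    read_len: int | None = None,
) -> ReadAnnotation:
    """Derive the ordered composition and per-read flags from filtered hits.

    The composition is emitted in canonical unit orientation (18S -> 28S):
    when the gene hits sit on the minus strand of the read, the label order
    is flipped. The IGS composition (labels between a 28S hit and the next
    18S hit in canonical orientation) is recorded when the read spans a
    complete spacer, else left as None.
    """
    if not hits:
        return ReadAnnotation(read_id="", read_len=read_len, me_free=True)
    ann = ReadAnnotation(
        read_id=hits[0].query.ref_id, read_len=read_len, hits=list(hits)
    )

    gene_hits = [h for h in hits if h.label in GENE_LABELS]
    vote_pool = gene_hits or hits
    minus_bp = sum(h.q_len() for h in vote_pool if h.query.strand == "-")
    plus_bp = sum(h.q_len() for h in vote_pool if h.query.strand == "+")
    ann.orientation = "-" if minus_bp > plus_bp else "+"

    ordered = sorted(hits, key=lambda h: h.query.start)
    if ann.orientation == "-":
        ordered = ordered[::-1]
    ann.composition = [h.label for h in ordered]

    for h in hits:
        ann.element_bp[h.label] = ann.element_bp.get(h.label, 0) + h.q_len()
    ann.satellite_bp = ann.element_bp.get("satellite", 0)

    # R2-type insertion inside (or splitting) a 28S hit
    host_hits = [h for h in hits if h.label == "28S"]
    for h in hits:
        if h.label not in insertion_labels:
            continue
        grown = Interval(
            h.query.ref_id,
            max(0, h.query.start - _INSERTION_SLOP),
            h.query.end + _INSERTION_SLOP,
            h.query.strand,
        )
        if any(grown.overlap(host.query) > 0 for host in host_hits):
            ann.has_r2_in_28S = True
            break

    mes = _element_labels(ann.element_bp)
    ann.me_free = not mes

    # full IGS spanned: a 28S followed (canonically) by an 18S
    labels = ann.composition
    for i, lab in enumerate(labels):
        if lab == "28S":
            for j in range(i + 1, len(labels)):
                if labels[j] == "18S":
                    igs = [
                        l
                        for l in labels[i + 1 : j]
                        if l not in GENE_LABELS and l not in insertion_labels
                    ]
                    ann.igs_composition = tuple(igs)
                    break
            if ann.igs_composition is not None:
                break
    return ann


@dataclass
class CohortSummary:
    n_reads: int = 0
    n_spanning_igs: int = 0
    modal_composition: tuple[str, ...] | None = None
    n_canonical: int = 0
    n_me_free: int = 0
    n_irregular: int = 0
    irregular_fraction: float | None = None
    reads_with_label: dict[str, int] = field(default_factory=dict)
    rdna_adjacent: dict[str, int] = field(default_factory=dict)
    n_full_28s: int = 0
    n_r2_in_28s: int = 0
    r2_read_fraction: float | None = None


def classify_cohort(
    annotations: list[ReadAnnotation],
    config: PipelineConfig,
    ref_28s_len: int | None = None,
    min_element_bp: int = 100,
    insertion_labels: tuple[str, ...] = INSERTION_LABELS,
    insertion_margin: int = 0,
) -> CohortSummary:
    """Cohort-level composition statistics.

    Only reads spanning a complete IGS vote for and are classified against
    the modal composition (truncated reads would otherwise masquerade as
    irregular). Element presence counts use a per-label minimum overlap:
    ``min_satellite_bp`` for the satellite, ``min_element_bp`` otherwise.

    The R2 read fraction is counted per fully-spanned 28S copy. With
    ``insertion_margin`` set to the insertion-element length, a copy is
    counted only when the read covers the whole insertion-capable window
    (gene length plus margin downstream of the gene's 5' edge): an inserted
    copy needs a longer read window to be seen complete, so without the
    margin empty copies are oversampled and the fraction is biased low.
    """
    if not annotations:
        raise ValueError("empty cohort")
    summary = CohortSummary(n_reads=len(annotations))

    spanning = [a for a in annotations if a.igs_composition is not None]
    summary.n_spanning_igs = len(spanning)
    if spanning:
        counts = Counter(a.igs_composition for a in spanning)
        top = max(counts.values())
        summary.modal_composition = min(c for c, n in counts.items() if n == top)
        for a in spanning:
            if a.igs_composition == summary.modal_composition:
                summary.n_canonical += 1
                a.irregular = False
            elif a.me_free and not a.satellite_bp:
                summary.n_me_free += 1
                a.irregular = False
            else:
                summary.n_irregular += 1
                a.irregular = True
        summary.irregular_fraction = summary.n_irregular / len(spanning)
    else:
        log.warning("no read spans a complete IGS; modal classification skipped")

    all_labels = {l for a in annotations for l in a.element_bp}
    for label in sorted(all_labels):
        min_bp = config.min_satellite_bp if label == "satellite" else min_element_bp
        summary.reads_with_label[label] = sum(
            1 for a in annotations if a.element_bp.get(label, 0) >= min_bp
        )
    gene_set = set(GENE_LABELS)
    for label in sorted(_element_labels(all_labels)):
        summary.rdna_adjacent[label] = sum(
            1
            for a in annotations
            if a.element_bp.get(label, 0) >= min_element_bp
            and any(g in a.element_bp for g in gene_set)
        )

    if ref_28s_len is not None:
        for a in annotations:
            for full, has_r2 in _28s_occurrences(
                a, ref_28s_len, insertion_labels, insertion_margin
            ):
                if full:
                    summary.n_full_28s += 1
                    if has_r2:
                        summary.n_r2_in_28s += 1
        if summary.n_full_28s:
            summary.r2_read_fraction = summary.n_r2_in_28s / summary.n_full_28s
    return summary


def _28s_occurrences(
    ann: ReadAnnotation,
    ref_len: int,
    insertion_labels: tuple[str, ...],
    insertion_margin: int = 0,
    max_insertion_span: int = 8000,
):
    """Group 28S hits (possibly split by an insertion) into gene copies.

    Yields (is_full, has_insertion) per copy; a copy is full when its summed
    28S bp reaches 90% of the reference gene length and, when a margin is
    requested, the read covers ``ref_len + insertion_margin`` bases downstream
    of the copy's canonical 5' edge (equal-opportunity window for inserted
    and empty copies).
    """
    hits28 = sorted(
        (h for h in ann.hits if h.label == "28S"), key=lambda h: h.query.start
    )
    inserts = [h for h in ann.hits if h.label in insertion_labels]
    groups: list[list[AlignmentHit]] = []
    for h in hits28:
        if groups and h.query.start - groups[-1][-1].query.end <= max_insertion_span:
            groups[-1].append(h)
        else:
            groups.append([h])
    for g in groups:
        bp = sum(h.q_len() for h in g)
        full = bp >= 0.9 * ref_len
        if full and insertion_margin > 0:
            window = ref_len + insertion_margin + _INSERTION_SLOP
            if ann.orientation == "+":
                full = g[0].query.start + window <= (ann.read_len or 0)
            else:
                full = g[-1].query.end - window >= 0
        span = Interval(
            g[0].query.ref_id,
            max(0, g[0].query.start - _INSERTION_SLOP),
            g[-1].query.end + _INSERTION_SLOP,
        )
        has_ins = any(span.overlap(h.query) > 0 for h in inserts)
        yield full, has_ins


def polish_consensus(
    reads: list[SequenceRecord],
    seed: str,
    config: PipelineConfig | None = None,
    min_depth: int = 3,
    max_low_cov_frac: float = 0.10,
) -> SequenceRecord:
    """Reference-guided majority-vote consensus over reads covering a region.

    Each read's overlap with the seed is located by anchoring and globally
    aligned; per seed column the majority symbol over {A,C,G,T,deletion}
    wins, with ties between bases broken in fixed order A<C<G<T and a
    deletion requiring a strict majority over all bases. An insertion
    between columns is emitted when more than half of the covering reads
    agree on having one (modal inserted sequence, lexicographic tie-break).
    """
    config = config or PipelineConfig()
    if len(reads) < 3:
        raise ValueError("consensus polishing needs at least 3 reads")
    n = len(seed)
    base_counts = [Counter() for _ in range(n)]
    ins_counts: dict[int, Counter] = {}
    coverage = [0] * n

    for read in reads:
        index = align.kmer_index(read.residues, config.anchor_k)
        placements = align.locate_both_strands(
            seed,
            read.residues,
            index,
            k=config.anchor_k,
            min_anchors=config.min_anchors,
            identity_floor=max(0.6, config.identity_floor - 0.1),
        )
        for p in placements:
            seg = read.residues[p.q_start : p.q_end]
            if p.strand == "-":
                seg = reverse_complement(seg)
            _tally(seed, p.s_start, p.s_end, seg, base_counts, ins_counts, coverage)

    low = sum(1 for c in coverage if c < min_depth)
    if low > max_low_cov_frac * n:
        gaps = [i for i, c in enumerate(coverage) if c < min_depth]
        raise ValueError(
            f"coverage below {min_depth} at {low}/{n} columns "
            f"(first gaps near {gaps[:5]})"
        )

    out: list[str] = []
    for i in range(n):
        ins = ins_counts.get(i)
        if ins and sum(ins.values()) * 2 > coverage[i] > 0:
            best = max(ins.values())
            out.append(min(s for s, c in ins.items() if c == best))
        counts = base_counts[i]
        if not counts:
            out.append(seed[i])  # uncovered column: keep the seed base
            continue
        dels = counts.get("-", 0)
        base_total = sum(v for k, v in counts.items() if k != "-")
        if dels > base_total:
            continue
        best = max(v for k, v in counts.items() if k != "-")
        out.append(
            min(k for k, v in counts.items() if k != "-" and v == best)
        )
    return SequenceRecord("consensus", "".join(out))


def _tally(seed, s_start, s_end, seg, base_counts, ins_counts, coverage):
    res = edlib.align(seed[s_start:s_end], seg, mode="NW", task="path")
    si = s_start  # seed column
    ri = 0  # segment position
    for num, op in align.cigar_walk(res["cigar"]):
        if op in ("=", "X"):
            for _ in range(num):
                base_counts[si][seg[ri]] += 1
                coverage[si] += 1
                si += 1
                ri += 1
        elif op == "I":  # seed base absent from the read: deletion
            for _ in range(num):
                base_counts[si]["-"] += 1
                coverage[si] += 1
                si += 1
        elif op == "D":  # read bases absent from the seed: insertion
            ins_counts.setdefault(si, Counter())[seg[ri : ri + num]] += 1
            ri += num
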