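"""Intragenomic rDNA sequence variability.

Gene regions (18S, ITS1, 5.8S, ITS2, 28S) are cut out of rDNA-bearing reads
that carry no R1/R2 insertion, clustered greedily at fixed identity
thresholds (the CD-HIT scheme: length-sorted, first-fit against cluster
representatives, identity = matches over the shorter sequence), and
summarised as identical-site and average pairwise identity statistics from
a reference-anchored alignment. Homogenised rDNA (concerted evolution)
shows up as few clusters and a high identical-site fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import cigar_walk, global_identity
from .annotate import INSERTION_LABELS, ReadAnnotation
from .core import GENE_LABELS, SequenceRecord, reverse_complement

__all__ = [
    "GeneRegionSet",
    "ClusterResult",
    "IdentityStats",
    "extract_gene_regions",
    "greedy_identity_cluster",
    "identity_stats",
]


@dataclass
class GeneRegionSet:
    label: str
    sequences: list[SequenceRecord] = field(default_factory=list)
    excluded_reads: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    threshold: float
    clusters: list[tuple[str, list[str]]]  # (representative id, member ids)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class IdentityStats:
    label: str
    avg_pairwise_identity: float
    pct_identical_sites: float


def extract_gene_regions(
    annotations: list[ReadAnnotation],
    reads: dict[str, SequenceRecord],
    refs: dict[str, str],
    insertion_labels: tuple[str, ...] = INSERTION_LABELS,
    min_fraction: float = 0.5,
) -> dict[str, GeneRegionSet]:
    """Per-gene sequence sets from non-R1/R2 rDNA reads.

    A gene hit contributes when it covers at least ``min_fraction`` of the
    reference region length; the read subsequence is emitted in canonical
    orientation. Reads carrying any insertion-element hit are excluded
    entirely (their units are pseudogenised and would inflate variability).
    """
    sets = {label: GeneRegionSet(label) for label in refs if label in GENE_LABELS}
    for ann in annotations:
        read = reads.get(ann.read_id)
        if read is None:
            continue
        if any(h.label in insertion_labels for h in ann.hits):
            for s in sets.values():
                s.excluded_reads.append(ann.read_id)
            continue
        counters: dict[str, int] = {}
        for h in ann.hits:
            if h.label not in sets:
                continue
            if h.q_len() < min_fraction * len(refs[h.label]):
                continue
            seq = read.residues[h.query.start : h.query.end]
            if h.query.strand == "-":
                seq = reverse_complement(seq)
            n = counters.get(h.label, 0)
            counters[h.label] = n + 1
            sets[h.label].sequences.append(
                SequenceRecord(f"{ann.read_id}/{h.label}.{n}", seq)
            )
    return sets


def greedy_identity_cluster(
    seqs: list[SequenceRecord], threshold: float
) -> ClusterResult:
    """Greedy incremental clustering at a fixed identity threshold.

    Sequences are taken longest-first (ties by id); each joins the first
    existing cluster, in creation order, whose representative it matches at
    ``identity >= threshold`` with identity defined as matching columns over
    the shorter sequence of a global alignment; otherwise it founds a new
    cluster and becomes its representative.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold outside (0, 1]")
    result = ClusterResult(threshold, [])
    reps: list[SequenceRecord] = []
    for seq in sorted(seqs, key=lambda s: (-len(s), s.id)):
        for k, rep in enumerate(reps):
            if global_identity(seq.residues, rep.residues) >= threshold:
                result.clusters[k][1].append(seq.id)
                break
        else:
            reps.append(seq)
            result.clusters.append((seq.id, [seq.id]))
    return result


def _anchored_rows(seqs: list[SequenceRecord], consensus: str) -> list[list[str]]:
    """Reference-anchored alignment: one row of consensus-length symbols per
    sequence ('-' for a deleted column, None outside the aligned span);
    insertions relative to the consensus are ignored."""
    n = len(consensus)
    rows = []
    for seq in seqs:
        res = edlib.align(seq.residues, consensus, mode="NW", task="path")
        row: list[str | None] = [None] * n
        si = 0  # sequence index
        ci = 0  # consensus column
        for num, op in cigar_walk(res["cigar"]):
            if op in ("=", "X"):
                for _ in range(num):
                    row[ci] = seq.residues[si]
                    si += 1
                    ci += 1
            elif op == "I":  # present in sequence only: insertion, ignored
                si += num
            elif op == "D":  # consensus column missing from sequence
                for _ in range(num):
                    row[ci] = "-"
                    ci += 1
        rows.append(row)
    return rows


def identity_stats(
    seqs: list[SequenceRecord], consensus: str, label: str = ""
) -> IdentityStats:
    """Identical-site fraction and average pairwise identity.

    A consensus column is identical when every sequence carries the same
    non-gap base there; the fraction is over all consensus columns. Pairwise
    identity for each pair is matching columns over columns where both carry
    a base, averaged over all pairs.
    """
    if len(seqs) < 2:
        raise ValueError("identity statistics need at least 2 sequences")
    rows = _anchored_rows(seqs, consensus)
    n = len(consensus)
    identical = 0
    for c in range(n):
        col = [row[c] for row in rows]
        if all(b is not None and b != "-" for b in col) and len(set(col)) == 1:
            identical += 1
    pct_identical = identical / n

    pair_ids = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            matches = aligned = 0
            for a, b in zip(rows[i], rows[j]):
                if a in (None, "-") or b in (None, "-"):
                    continue
                aligned += 1
                if a == b:
                    matches += 1
            pair_ids.append(matches / aligned if aligned else 0.0)
    return IdentityStats(label, sum(pair_ids) / len(pair_ids), pct_identical)
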