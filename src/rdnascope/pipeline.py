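"""End-to-end orchestration: mine -> annotate -> satellites -> variability
-> coverage, with a per-species report mirroring the long-read and coverage
results a study of rDNA cluster architecture tabulates.

All stages are pure functions of their inputs and the config seed, so a run
with the same inputs and seed is byte-identical; the manifest records the
effective config and input checksums to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import annotate as ann_mod
from . import coverage as cov_mod
from . import mining, satellites, variability
from .core import AnnotationBlock, PipelineConfig, SequenceRecord

__all__ = ["PipelineInputs", "SpeciesReport", "RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    long_reads: list[SequenceRecord]
    gene_refs: dict[str, str]
    library: dict[str, str]
    short_reads: tuple[list[SequenceRecord], list[SequenceRecord]] | None = None
    unit_consensus: SequenceRecord | None = None
    unit_blocks: list[AnnotationBlock] | None = None
    microsat_motifs: list[str] = field(default_factory=list)
    insertion_labels: tuple[str, ...] = ann_mod.INSERTION_LABELS


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    rng_seed: int

    @staticmethod
    def build(config: PipelineConfig, inputs: PipelineInputs) -> "RunManifest":
        def digest(items) -> str:
            h = hashlib.sha256()
            for it in items:
                h.update(str(it).encode())
            return h.hexdigest()[:16]

        sums = {
            "long_reads": digest((r.id, r.residues) for r in inputs.long_reads),
            "gene_refs": digest(sorted(inputs.gene_refs.items())),
            "library": digest(sorted(inputs.library.items())),
        }
        if inputs.short_reads:
            sums["short_reads"] = digest(
                (r.id, r.residues) for mates in inputs.short_reads for r in mates
            )
        return RunManifest(dataclasses.asdict(config), sums, config.rng_seed)


@dataclass
class SpeciesReport:
    n_reads_input: int = 0
    n_reads_filtered: int = 0
    n_rdna_reads: int = 0
    reads_with_label: dict[str, int] = field(default_factory=dict)
    rdna_adjacent: dict[str, int] = field(default_factory=dict)
    n_r2_in_28s_reads: int = 0
    r2_read_fraction: float | None = None
    n_me_free: int = 0
    n_canonical: int = 0
    n_irregular: int = 0
    irregular_fraction: float | None = None
    modal_composition: list[str] | None = None
    n_satellite_arrays: int = 0
    satellite_median_bp: float | None = None
    satellite_max_bp: int | None = None
    n_satellite_only_reads: int = 0
    cluster_counts: dict[str, int] = field(default_factory=dict)  # "label@thr"
    identity: dict[str, dict[str, float]] = field(default_factory=dict)
    block_means: dict[str, float] = field(default_factory=dict)
    insertion_fractions: dict[str, float] = field(default_factory=dict)
    genome_proportion: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs
) -> tuple[SpeciesReport, dict]:
    """Run every stage and collect the species report.

    Coverage statistics are computed only when short reads and a unit
    consensus are supplied. Returns the report plus an artifact dict with
    the intermediate per-stage objects (filter results, rDNA calls,
    annotations, arrays, cluster results, coverage profile, manifest).
    """
    report = SpeciesReport(n_reads_input=len(inputs.long_reads))
    artifacts: dict = {"manifest": RunManifest.build(config, inputs)}

    # --- mine ---------------------------------------------------------
    filt = mining.filter_reads(inputs.long_reads, config)
    artifacts["filter_results"] = filt
    passed_ids = {f.read_id for f in filt if f.passed}
    passed = [r for r in inputs.long_reads if r.id in passed_ids]
    report.n_reads_filtered = len(passed)
    log.info("filtered: %d of %d reads pass", len(passed), len(inputs.long_reads))

    calls = {r.id: mining.detect_rdna(r, inputs.gene_refs, config) for r in passed}
    artifacts["rdna_calls"] = calls
    is_rdna = {rid: c.is_rdna for rid, c in calls.items()}
    rdna_reads = [r for r in passed if is_rdna[r.id]]
    report.n_rdna_reads = len(rdna_reads)
    log.info("rDNA-bearing reads: %d", len(rdna_reads))

    # --- annotate -----------------------------------------------------
    annotations: list[ann_mod.ReadAnnotation] = []
    for read in passed:
        hits = ann_mod.map_library(read, inputs.library, config)
        hits = ann_mod.filter_and_merge_hits(hits, config)
        a = ann_mod.compose_read(hits, inputs.insertion_labels, read_len=len(read))
        if not a.read_id:
            a.read_id = read.id
        annotations.append(a)
    artifacts["annotations"] = annotations
    rdna_annotations = [a for a in annotations if is_rdna.get(a.read_id, False)]

    if rdna_annotations:
        margin = max(
            (
                len(inputs.library[l])
                for l in inputs.insertion_labels
                if l in inputs.library
            ),
            default=0,
        )
        summary = ann_mod.classify_cohort(
            rdna_annotations,
            config,
            ref_28s_len=len(inputs.gene_refs.get("28S", "")) or None,
            insertion_labels=inputs.insertion_labels,
            insertion_margin=margin,
        )
        artifacts["cohort"] = summary
        report.reads_with_label = summary.reads_with_label
        report.rdna_adjacent = summary.rdna_adjacent
        report.n_r2_in_28s_reads = sum(1 for a in rdna_annotations if a.has_r2_in_28S)
        report.r2_read_fraction = summary.r2_read_fraction
        report.n_me_free = summary.n_me_free
        report.n_canonical = summary.n_canonical
        report.n_irregular = summary.n_irregular
        report.irregular_fraction = summary.irregular_fraction
        if summary.modal_composition is not None:
            report.modal_composition = list(summary.modal_composition)

    # --- satellites ---------------------------------------------------
    arrays: list[satellites.SatelliteArray] = []
    if "satellite" in inputs.library:
        for read in passed:
            for arr in satellites.detect_tandem_arrays(
                read.residues, seq_id=read.id
            ):
                arrays.append(arr)
        stats = satellites.array_length_stats(arrays, annotations, is_rdna, config)
        artifacts["arrays"] = arrays
        artifacts["array_stats"] = stats
        report.n_satellite_arrays = stats.n_arrays
        report.satellite_median_bp = stats.median
        report.satellite_max_bp = stats.maximum
        report.n_satellite_only_reads = stats.n_satellite_only_reads

    # --- variability --------------------------------------------------
    read_map = {r.id: r for r in rdna_reads}
    regions = variability.extract_gene_regions(
        rdna_annotations, read_map, inputs.gene_refs, inputs.insertion_labels
    )
    artifacts["gene_regions"] = regions
    for label, rset in regions.items():
        for thr in config.identity_thresholds:
            res = variability.greedy_identity_cluster(rset.sequences, thr)
            report.cluster_counts[f"{label}@{thr:.2f}"] = res.n_clusters
        if len(rset.sequences) >= 2:
            st = variability.identity_stats(
                rset.sequences, inputs.gene_refs[label], label
            )
            report.identity[label] = {
                "avg_pairwise_identity": st.avg_pairwise_identity,
                "pct_identical_sites": st.pct_identical_sites,
            }

    # --- coverage -----------------------------------------------------
    if inputs.short_reads is not None and inputs.unit_consensus is not None:
        m1, m2 = mining.preprocess_short_reads(*inputs.short_reads, config)
        depth = cov_mod.compute_depth(
            m1 + m2, inputs.unit_consensus, config, seed=config.rng_seed
        )
        smoothed = cov_mod.loess_smooth(depth, config.loess_span)
        profile = cov_mod.CoverageProfile(
            inputs.unit_consensus.id, depth, smoothed
        )
        if inputs.unit_blocks:
            profile.block_means = cov_mod.block_means(depth, inputs.unit_blocks)
            report.block_means = profile.block_means
            host = "28S"
            for label in inputs.insertion_labels:
                if label in profile.block_means and host in profile.block_means:
                    est = cov_mod.insertion_fraction(profile, label, host)
                    report.insertion_fractions[f"{label}/{host}"] = est.fraction
        artifacts["coverage"] = profile

    return report, artifacts
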