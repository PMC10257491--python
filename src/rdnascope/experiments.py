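"""Planted-truth benchmark experiments over the synthetic landscapes.

Each function sets up one study condition — a landscape profile, a read
simulation, a pipeline run — and scores the pipeline against the planted
truth. These are the package's quantitative validation surface: the
analysis drivers and the acceptance script call them, and the test suite
asserts their tolerances.

Problem sizes (read counts, depths, unit counts) are the package's chosen
desk-scale study conditions; they are documented in the methods note.
"""

from __future__ import annotations

import hashlib

import numpy as np

from . import annotate as ann_mod
from . import coverage as cov_mod
from . import mining, satellites, variability
from .core import GENE_LABELS, Interval, PipelineConfig, SequenceRecord
from .simulate import (
    ReadSimParams,
    SatelliteSpec,
    SpeciesProfile,
    build_landscape,
    builtin_profile,
    simulate_reads,
    unit_consensus,
)

__all__ = [
    "hhumuli_compact_profile",
    "iio_like_profile",
    "annotate_reads",
    "mining_benchmark",
    "composition_benchmark",
    "irregular_benchmark",
    "r2_read_benchmark",
    "r2_coverage_benchmark",
    "satellite_benchmark",
    "satellite_only_benchmark",
    "clustering_benchmark",
    "coverage_machinery_check",
    "determinism_check",
]

_GENES = {"18S": 1900, "ITS1": 550, "5.8S": 160, "ITS2": 600, "28S": 3900}


def hhumuli_compact_profile(
    irregular_fraction: float = 0.0, n_units: int = 50
) -> SpeciesProfile:
    """Eight-element IGS architecture with compact element fragments.

    Keeps the ghost-moth element inventory but shrinks the spacer so that a
    large fraction of unit-length reads span a complete IGS — the geometry
    needed to estimate the irregular-read fraction precisely from a cohort
    of a few hundred reads.
    """
    return SpeciesProfile(
        name="hhumuli_compact",
        gene_lengths=dict(_GENES),
        igs_elements=[
            ("Ty3_gypsyA", 500),
            ("Ty3_gypsyB", 400),
            ("Ty3_gypsyC", 300),
            ("L2", 600),
            ("RTE_RTE", 250),
            ("PIF_Harbinger", 300),
            ("PIF_Spy", 350),
            ("P_element", 400),
        ],
        n_units=n_units,
        unit_divergence=0.002,
        igs_spacer_len=60,
        flank_len=3000,
        irregular_fraction=irregular_fraction,
    )


def iio_like_profile(
    f: float = 1 / 3, n_units: int = 30, satellite_copies=(40, 70)
) -> SpeciesProfile:
    """Peacock-butterfly-like unit: 157 bp IGS satellite and an R2-type
    element inserted in a fraction ``f`` of 28S copies.

    The default satellite copy range keeps every unit longer than the read
    cap used in the benchmarks, the regime of the real species (units exceed
    filtered read lengths), so no read sees two copies of one unit region
    and the uniqueness filter never censors copies.
    """
    return SpeciesProfile(
        name="iio_like",
        gene_lengths=dict(_GENES),
        satellite=SatelliteSpec(
            monomer_len=157, copies_range=satellite_copies, copy_divergence=0.02
        ),
        r2_insertion_fraction=f,
        r2_length=3000,
        n_units=n_units,
        unit_divergence=0.002,
        igs_spacer_len=500,
        flank_len=3000,
    )


def annotate_reads(reads, truth, config: PipelineConfig):
    """Map the truth library (+ gene references) and compose each read."""
    library = dict(truth.repeat_library)
    library.update(truth.gene_refs)
    insertion_labels = (truth.profile.r2_label,)
    annotations = []
    for read in reads:
        hits = ann_mod.map_library(read, library, config)
        hits = ann_mod.filter_and_merge_hits(hits, config)
        a = ann_mod.compose_read(hits, insertion_labels, read_len=len(read))
        if not a.read_id:
            a.read_id = read.id
        annotations.append(a)
    return annotations


# ---------------------------------------------------------------- mining


def mining_benchmark(seed: int, n_reads: int = 500) -> dict:
    """rDNA read classification vs planted truth.

    Error-free reads score recall and precision of the >=1 kb-of-rDNA rule
    against the truth gene-block overlap; ONT-like reads (7% error) score
    recall on reads truly overlapping >=2 kb of gene blocks.
    """
    config = PipelineConfig()
    truth = build_landscape(builtin_profile("hepialus_humuli"), seed)

    out: dict = {}
    for err, mean_q, key in ((0.0, 20, "e0"), (0.07, 12, "ont")):
        params = ReadSimParams(
            mode="long",
            n_reads=n_reads,
            median_len=18000,
            sigma=0.25,
            error_rate=err,
            mean_q=mean_q,
        )
        reads, rtruth = simulate_reads(truth, params, seed + 1)
        tp = fp = fn = tn = 0
        rec2k = n2k = 0
        for read, rt in zip(reads, rtruth):
            call = mining.detect_rdna(read, truth.gene_refs, config)
            true_bp = truth.gene_bp_in(rt.origin.start, rt.origin.end)
            is_true = true_bp >= config.min_rdna_bp
            tp += call.is_rdna and is_true
            fp += call.is_rdna and not is_true
            fn += (not call.is_rdna) and is_true
            tn += (not call.is_rdna) and not is_true
            if true_bp >= 2000:
                n2k += 1
                rec2k += call.is_rdna
        out[f"recall_{key}"] = tp / (tp + fn) if (tp + fn) else 1.0
        out[f"precision_{key}"] = tp / (tp + fp) if (tp + fp) else 1.0
        out[f"recall2k_{key}"] = rec2k / n2k if n2k else 1.0
        out[f"n_{key}"] = n_reads
    return out


# ----------------------------------------------------------- composition


def composition_benchmark(seed: int, n_reads: int = 150) -> dict:
    """Per-read ordered composition vs truth on error-free ghost-moth reads.

    A read's observed element order must equal the truth-block order over
    its origin interval (elements overlapping the read by at least 100 bp).
    """
    config = PipelineConfig()
    truth = build_landscape(builtin_profile("hepialus_humuli"), seed)
    unit_len = truth.unit_bounds[0][1] - truth.unit_bounds[0][0]
    params = ReadSimParams(
        mode="long",
        n_reads=n_reads,
        median_len=20000,
        sigma=0.10,
        max_len=unit_len - 200,
        error_rate=0.0,
        mean_q=20,
    )
    reads, rtruth = simulate_reads(truth, params, seed + 1)
    annotations = annotate_reads(reads, truth, config)

    # canonical orientation equals genome order (units are built 18S -> 28S),
    # so observed canonical compositions compare directly with truth order
    skip = set(GENE_LABELS) | {"IGS"}
    exact = 0
    for ann, rt in zip(annotations, rtruth):
        s, e = rt.origin.start, rt.origin.end
        expected = [
            b.label
            for b in truth.blocks_overlapping(s, e)
            if b.label not in skip and min(b.end, e) - max(b.start, s) >= 100
        ]
        ordered = sorted(ann.hits, key=lambda h: h.query.start)
        if ann.orientation == "-":
            ordered = ordered[::-1]
        observed = [
            h.label for h in ordered if h.label not in skip and h.q_len() >= 100
        ]
        exact += observed == expected
    return {"fraction_exact": exact / len(reads), "n": len(reads)}


def irregular_benchmark(seed: int, n_reads: int = 500, n_replicates: int = 3) -> dict:
    """Recovery of a planted 12% shuffled-IGS unit fraction.

    The per-cohort classification is exact (a spanning read is irregular iff
    its spanned IGS belongs to a shuffled unit), so the only error is which
    units the 500 reads happen to sample — binomial noise of ~1.9 points.
    The experiment therefore averages independent replicate cohorts; each
    cohort is the stated 500-read condition.
    """
    config = PipelineConfig()
    estimates = []
    n_spanning = 0
    planted = None
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        profile = hhumuli_compact_profile(irregular_fraction=0.12)
        truth = build_landscape(profile, rep_seed)
        unit_len = truth.unit_bounds[0][1] - truth.unit_bounds[0][0]
        params = ReadSimParams(
            mode="long",
            n_reads=n_reads,
            median_len=int(unit_len * 0.97),
            sigma=0.10,
            max_len=unit_len - 150,
            error_rate=0.0,
            mean_q=20,
        )
        reads, _ = simulate_reads(truth, params, rep_seed + 1)
        annotations = annotate_reads(reads, truth, config)
        summary = ann_mod.classify_cohort(
            annotations, config, ref_28s_len=_GENES["28S"]
        )
        estimates.append(summary.irregular_fraction)
        n_spanning += summary.n_spanning_igs
        planted = len(truth.irregular_units) / profile.n_units
    return {
        "planted": planted,
        "estimate": float(np.mean(estimates)),
        "replicates": estimates,
        "n_spanning": n_spanning,
        "n": n_reads,
    }


# ------------------------------------------------------------------- R2


def r2_read_benchmark(
    seed: int, f: float = 1 / 3, n_reads: int = 800, n_replicates: int = 2
) -> dict:
    """Read-count estimate of the 28S insertion fraction.

    Counts insertion status per fully-sampled 28S copy with the
    equal-opportunity window (see classify_cohort); averaged over replicate
    cohorts to tame the per-copy binomial sampling noise.
    """
    config = PipelineConfig()
    estimates = []
    n_full = 0
    planted = None
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        profile = iio_like_profile(f=f)
        truth = build_landscape(profile, rep_seed)
        params = ReadSimParams(
            mode="long",
            n_reads=n_reads,
            median_len=12500,
            sigma=0.10,
            max_len=13500,
            error_rate=0.0,
            mean_q=20,
        )
        reads, _ = simulate_reads(truth, params, rep_seed + 1)
        annotations = annotate_reads(reads, truth, config)
        summary = ann_mod.classify_cohort(
            annotations,
            config,
            ref_28s_len=_GENES["28S"],
            insertion_labels=(profile.r2_label,),
            insertion_margin=profile.r2_length,
        )
        estimates.append(summary.r2_read_fraction)
        n_full += summary.n_full_28s
        planted = len(truth.r2_units) / profile.n_units
    return {
        "planted": planted,
        "estimate": float(np.mean(estimates)),
        "replicates": estimates,
        "n_full_28s": n_full,
        "n": n_reads,
    }


def r2_coverage_benchmark(seed: int, f: float = 1 / 3, depth: float = 50) -> dict:
    """Coverage-ratio estimate of the 28S insertion fraction at ~50x."""
    config = PipelineConfig()
    profile = SpeciesProfile(
        name="r2cov",
        gene_lengths=dict(_GENES),
        r2_insertion_fraction=f,
        r2_length=3000,
        n_units=12,
        unit_divergence=0.002,
        igs_spacer_len=1500,
        flank_len=3000,
    )
    truth = build_landscape(profile, seed)
    cons, blocks = unit_consensus(truth)
    locus_bp = sum(b - a for a, b in truth.unit_bounds)
    g_len = len(truth.genome.residues)
    n_pairs = int(depth * len(cons) * g_len / locus_bp / (2 * config.short_read_trim_len))
    params = ReadSimParams(
        mode="paired",
        n_reads=n_pairs,
        read_len=150,
        insert_size=450,
        error_rate=0.002,
        mean_q=30,
    )
    reads, _ = simulate_reads(truth, params, seed + 1)
    m1, m2 = mining.preprocess_short_reads(reads[0::2], reads[1::2], config)
    depth_vec = cov_mod.compute_depth(m1 + m2, cons, config, seed=seed)
    means = cov_mod.block_means(depth_vec, blocks)
    profile_cov = cov_mod.CoverageProfile(cons.id, depth_vec, depth_vec, means)
    est = cov_mod.insertion_fraction(profile_cov, profile.r2_label, "28S")
    return {
        "planted": len(truth.r2_units) / profile.n_units,
        "estimate": est.fraction,
        "mean_28s_depth": means["28S"],
        "n": n_pairs,
    }


# ------------------------------------------------------------ satellites


def satellite_benchmark(
    seed: int,
    monomers: tuple[int, ...] = (157, 252, 258, 400),
    divergence: float = 0.05,
    n_copies: int = 15,
) -> dict:
    """Monomer-length recovery for the reported satellite monomer sizes."""
    from .simulate import _mutate, _random_seq  # reuse the generator's mutator

    rng = np.random.default_rng(seed)
    out = {}
    for mlen in monomers:
        monomer = _random_seq(rng, mlen)
        array = "".join(_mutate(rng, monomer, divergence) for _ in range(n_copies))
        seq = _random_seq(rng, 800) + array + _random_seq(rng, 800)
        arrays = detect = satellites.detect_tandem_arrays(seq)
        est = max(detect, key=lambda a: a.n_copies).monomer_len if arrays else 0
        out[int(mlen)] = est
    return out


def satellite_only_benchmark(seed: int, n_planted: int = 30, n_locus_reads: int = 150) -> dict:
    """Exact recovery of planted satellite-only reads at zero error.

    Locus reads come from an IGS-satellite landscape; the planted extras are
    drawn from a pure satellite contig (no rDNA, no elements), mirroring
    reads from satellite arrays outside the rDNA cluster. The locus satellite
    arrays are kept shorter than the shortest simulated read so that no locus
    read can itself be satellite-only and the planted count is the exact
    truth.
    """
    config = PipelineConfig()
    profile = iio_like_profile(f=0.0, satellite_copies=(30, 45))
    truth = build_landscape(profile, seed)
    params = ReadSimParams(
        mode="long",
        n_reads=n_locus_reads,
        median_len=12500,
        sigma=0.10,
        max_len=13500,
        error_rate=0.0,
        mean_q=20,
    )
    reads, _ = simulate_reads(truth, params, seed + 1)

    from .simulate import _build_satellite_array

    rng = np.random.default_rng(seed + 2)
    monomer = truth.repeat_library["satellite"]
    sat_reads = []
    for i in range(n_planted):
        n_cop = int(rng.integers(20, 60))
        arr = _build_satellite_array(rng, profile.satellite, monomer, n_cop)
        sat_reads.append(SequenceRecord(f"satonly{i:03d}", arr, [20] * len(arr)))

    all_reads = reads + sat_reads
    annotations = annotate_reads(all_reads, truth, config)
    is_rdna = {
        r.id: mining.detect_rdna(r, truth.gene_refs, config).is_rdna
        for r in all_reads
    }
    arrays = []
    for r in all_reads:
        arrays.extend(satellites.detect_tandem_arrays(r.residues, seq_id=r.id))
    stats = satellites.array_length_stats(arrays, annotations, is_rdna, config)
    return {
        "planted": n_planted,
        "recovered": stats.n_satellite_only_reads,
        "median_array_bp": stats.median,
        "max_array_bp": stats.maximum,
        "n_arrays": stats.n_arrays,
    }


# ------------------------------------------------------------ clustering


def clustering_benchmark(seed: int, n_per_family: int = 10) -> dict:
    """Two planted subfamilies: cluster counts at 95%/80% and monotonicity."""
    from .simulate import _mutate, _random_seq

    rng = np.random.default_rng(seed)
    base = _random_seq(rng, 500)
    other = _mutate(rng, base, 0.10)
    seqs = []
    for i in range(n_per_family):
        seqs.append(SequenceRecord(f"a{i:02d}", _mutate(rng, base, 0.01)))
        seqs.append(SequenceRecord(f"b{i:02d}", _mutate(rng, other, 0.01)))
    counts = {}
    for thr in (0.95, 0.90, 0.85, 0.80):
        counts[thr] = variability.greedy_identity_cluster(seqs, thr).n_clusters
    monotone = all(
        counts[a] >= counts[b]
        for a, b in zip((0.95, 0.90, 0.85), (0.90, 0.85, 0.80))
    )
    return {
        "clusters_95": counts[0.95],
        "clusters_80": counts[0.80],
        "monotone": monotone,
        "n_seqs": len(seqs),
    }


# -------------------------------------------------------------- coverage


def coverage_machinery_check(seed: int) -> dict:
    """Depth conservation, LOESS exactness on constants/lines, block means."""
    config = PipelineConfig()
    profile = SpeciesProfile(
        name="covchk",
        gene_lengths={"18S": 1000, "ITS1": 300, "5.8S": 160, "ITS2": 300, "28S": 2000},
        n_units=4,
        unit_divergence=0.001,
        igs_spacer_len=800,
        flank_len=1500,
    )
    truth = build_landscape(profile, seed)
    cons, blocks = unit_consensus(truth)
    params = ReadSimParams(
        mode="paired", coverage=8, read_len=150, insert_size=450,
        error_rate=0.002, mean_q=30,
    )
    reads, _ = simulate_reads(truth, params, seed + 1)
    m1, m2 = mining.preprocess_short_reads(reads[0::2], reads[1::2], config)
    depth, alignments = cov_mod.compute_depth(
        m1 + m2, cons, config, seed=seed, return_alignments=True
    )
    aligned_bp = sum(alen for *_, alen in alignments)
    conservation_gap = abs(int(depth.sum()) - aligned_bp)

    rng = np.random.default_rng(seed)
    const = np.full(600, 30.0)
    line = np.arange(600, dtype=float) * 0.5 + 3
    const_err = float(np.abs(cov_mod.loess_smooth(const, 0.1) - const).max())
    line_err = float(np.abs(cov_mod.loess_smooth(line, 0.1) - line).max())

    noisy = rng.poisson(30, size=len(cons)).astype(float)
    means = cov_mod.block_means(noisy, blocks)
    # brute-force oracle: mean over the union of each label's positions
    pos: dict[str, set] = {}
    for b in blocks:
        pos.setdefault(b.label, set()).update(range(b.start, b.end))
    oracle = {k: float(np.mean([noisy[i] for i in sorted(v)])) for k, v in pos.items()}
    block_err = max(abs(means[k] - oracle[k]) for k in means)
    return {
        "depth_conservation_gap": conservation_gap,
        "loess_const_max_err": const_err,
        "loess_line_max_err": line_err,
        "block_means_max_err": float(block_err),
        "mean_depth": float(depth.mean()),
    }


# ----------------------------------------------------------- determinism


def determinism_check(seed: int, n_reads: int = 80) -> dict:
    """Two identical runs must produce byte-identical reports."""
    from .pipeline import PipelineInputs, run_pipeline

    digests = []
    for _ in range(2):
        config = PipelineConfig(rng_seed=seed)
        truth = build_landscape(iio_like_profile(f=1 / 3, n_units=8), seed)
        params = ReadSimParams(
            mode="long", n_reads=n_reads, median_len=14000, sigma=0.12,
            max_len=15000, error_rate=0.01, mean_q=20,
        )
        reads, _ = simulate_reads(truth, params, seed + 1)
        library = dict(truth.repeat_library)
        library.update(truth.gene_refs)
        inputs = PipelineInputs(
            long_reads=reads, gene_refs=truth.gene_refs, library=library,
            insertion_labels=(truth.profile.r2_label,),
        )
        config = PipelineConfig(rng_seed=seed, min_read_length=10_000)
        report, _ = run_pipeline(config, inputs)
        digests.append(hashlib.sha256(report.to_json().encode()).hexdigest())
    return {"identical": digests[0] == digests[1], "digest": digests[0][:12]}
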