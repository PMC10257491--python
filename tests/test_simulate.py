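"""Synthetic landscape generator: planted truth must be exact and reproducible."""

import numpy as np
import pytest

from rdnascope import seqio
from rdnascope.core import reverse_complement
from rdnascope.simulate import (
    ReadSimParams,
    SatelliteSpec,
    SpeciesProfile,
    build_landscape,
    builtin_profile,
    simulate_reads,
    unit_consensus,
)

GENES = {"18S": 800, "ITS1": 200, "5.8S": 120, "ITS2": 200, "28S": 1500}


def test_f_zero_plants_no_r2():
    prof = SpeciesProfile(name="x", gene_lengths=GENES, n_units=10,
                          r2_insertion_fraction=0.0)
    truth = build_landscape(prof, seed=1)
    assert not truth.r2_units
    assert all(b.label != "R2" for b in truth.blocks)


@pytest.mark.parametrize("f", [0.0, 1 / 3, 0.5, 1.0])
def test_planted_r2_fraction_exact(f):
    prof = SpeciesProfile(name="x", gene_lengths=GENES, n_units=12,
                          r2_insertion_fraction=f, r2_length=600)
    truth = build_landscape(prof, seed=2)
    n_r2_blocks = sum(1 for b in truth.blocks if b.label == "R2")
    assert n_r2_blocks == round(f * 12)
    assert len(truth.r2_units) == round(f * 12)


def test_eight_element_igs_order_per_unit():
    """Every unit's IGS lists the configured element labels in order."""
    prof = builtin_profile("hepialus_humuli")
    truth = build_landscape(prof, seed=3)
    expected = [label for label, _ in prof.igs_elements]
    element_set = set(expected)
    for start, end in truth.unit_bounds:
        labels = [
            b.label
            for b in truth.blocks
            if b.start >= start and b.end <= end and b.label in element_set
        ]
        assert labels == expected


def test_satellite_block_lengths_divisible_by_monomer():
    prof = SpeciesProfile(
        name="iio",
        gene_lengths=GENES,
        satellite=SatelliteSpec(monomer_len=157, copies_range=(8, 20)),
        n_units=10,
    )
    truth = build_landscape(prof, seed=4)
    sat_blocks = [b for b in truth.blocks if b.label == "satellite"]
    assert len(sat_blocks) == 10
    for b in sat_blocks:
        assert len(b.interval) % 157 == 0
        assert 8 <= len(b.interval) // 157 <= 20


def test_gene_blocks_in_canonical_order():
    truth = build_landscape(SpeciesProfile(name="x", gene_lengths=GENES, n_units=3), 5)
    for start, end in truth.unit_bounds:
        genes = [
            b.label
            for b in truth.blocks
            if b.start >= start and b.end <= end and b.label in GENES
        ]
        assert genes == ["18S", "ITS1", "5.8S", "ITS2", "28S"]


def test_truth_blocks_tile_units_without_overlap():
    prof = SpeciesProfile(
        name="x", gene_lengths=GENES,
        igs_elements=[("e1", 300)], n_units=4,
        satellite=SatelliteSpec(monomer_len=50, copies_range=(4, 6)),
    )
    truth = build_landscape(prof, seed=6)
    for start, end in truth.unit_bounds:
        blocks = sorted(
            (b for b in truth.blocks if b.start >= start and b.end <= end),
            key=lambda b: b.start,
        )
        assert blocks[0].start == start
        assert blocks[-1].end == end
        for a, b in zip(blocks, blocks[1:]):
            assert a.end == b.start


def test_error_free_reads_are_genome_substrings(small_truth, small_reads):
    reads, rtruth = small_reads
    genome = small_truth.genome.residues
    for read, rt in zip(reads, rtruth):
        template = genome[rt.origin.start : rt.origin.end]
        if rt.strand == "-":
            template = reverse_complement(template)
        assert read.residues == template


def test_substitution_count_binomial(small_truth):
    """Observed substitutions stay within 3 SD of Binomial(L, e*p_sub).

    Simulated with a substitution-only error split so mismatches can be
    counted positionally without alignment.
    """
    genome = small_truth.genome.residues
    params_sub = ReadSimParams(
        mode="long", n_reads=100, median_len=10_000, sigma=0.01,
        error_rate=0.03, error_split=(1.0, 0.0, 0.0), mean_q=12,
    )
    reads2, rtruth2 = simulate_reads(small_truth, params_sub, seed=8)
    subs = 0
    n = 0
    for read, rt in zip(reads2, rtruth2):
        template = genome[rt.origin.start : rt.origin.end]
        if rt.strand == "-":
            template = reverse_complement(template)
        subs += sum(a != b for a, b in zip(read.residues, template))
        n += len(template)
    exp, sd = n * 0.03, np.sqrt(n * 0.03 * 0.97)
    assert abs(subs - exp) <= 3 * sd


def test_paired_mode_mate_gap(small_truth):
    params = ReadSimParams(mode="paired", n_reads=5, read_len=150, insert_size=450)
    reads, rtruth = simulate_reads(small_truth, params, seed=9)
    genome = small_truth.genome.residues
    for i in range(0, 10, 2):
        frag = rtruth[i].origin
        assert len(frag) == 450
        r1, r2 = reads[i], reads[i + 1]
        assert r1.residues == genome[frag.start : frag.start + 150]
        assert r2.residues == reverse_complement(genome[frag.end - 150 : frag.end])
        # mate gap on truth coordinates = insert - 2*read_len
        assert (frag.end - 150) - (frag.start + 150) == 150


def test_zero_coverage_is_empty_not_error(small_truth):
    params = ReadSimParams(mode="long", n_reads=0, median_len=5000)
    reads, rtruth = simulate_reads(small_truth, params, seed=1)
    assert reads == [] and rtruth == []


def test_regeneration_same_seed_byte_identical(tmp_path, small_profile):
    files = []
    for run in range(2):
        truth = build_landscape(small_profile, seed=11)
        params = ReadSimParams(mode="long", n_reads=15, median_len=4000,
                               error_rate=0.05, mean_q=12)
        reads, _ = simulate_reads(truth, params, seed=12)
        path = tmp_path / f"run{run}.fastq"
        seqio.write_fastq(reads, path)
        files.append(path.read_bytes())
    assert files[0] == files[1]


def test_truth_bed_roundtrip(tmp_path, small_truth):
    path = tmp_path / "truth.bed"
    seqio.write_bed(small_truth.blocks, path)
    back = seqio.read_bed(path, source="truth")
    assert [(b.label, b.start, b.end) for b in back] == [
        (b.label, b.start, b.end) for b in small_truth.blocks
    ]


def test_mean_read_quality_near_target(small_truth):
    from rdnascope.mining import mean_read_quality

    params = ReadSimParams(mode="long", n_reads=20, median_len=5000, mean_q=20)
    reads, _ = simulate_reads(small_truth, params, seed=13)
    for r in reads:
        assert abs(mean_read_quality(r.qualities) - 20) <= 1.0


def test_unit_consensus_prefers_r2_unit():
    prof = SpeciesProfile(name="x", gene_lengths=GENES, n_units=6,
                          r2_insertion_fraction=0.5, r2_length=500)
    truth = build_landscape(prof, seed=14)
    cons, blocks = unit_consensus(truth)
    assert any(b.label == "R2" for b in blocks)
    start, end = truth.unit_bounds[truth.r2_units[0]]
    assert len(cons) == end - start


def test_oversized_profile_rejected():
    prof = SpeciesProfile(
        name="huge", gene_lengths={"18S": 30_000_000, "ITS1": 1, "5.8S": 1,
                                   "ITS2": 1, "28S": 1},
        n_units=4,
    )
    with pytest.raises(ValueError, match="exceeds"):
        build_landscape(prof, seed=1)


def test_telomere_flank_present():
    prof = SpeciesProfile(name="x", gene_lengths=GENES, n_units=2,
                          telomere_flank=True, flank_len=2000)
    truth = build_landscape(prof, seed=15)
    assert truth.genome.residues.startswith("TTAGG" * 10)
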