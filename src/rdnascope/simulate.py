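"""Synthetic rDNA landscapes with known truth, and read simulation.

A landscape is a tandem array of major rDNA units (18S-ITS1-5.8S-ITS2-28S
followed by the intergenic spacer, IGS). Per species profile the IGS carries
mobile-element fragments, a satellite array of variable copy number and/or
microsatellite runs; a configurable fraction of units carries an R2-type
retrotransposon inserted at a fixed site inside 28S. Long or paired short
reads are drawn from the landscape with a simple per-base error model, so
every downstream stage can be scored against planted truth.

Element *fragments* are simulated as 5'- or 3'-truncated copies of a
full-length consensus: the annotation library holds the full consensus while
the genome carries only the fragment, mirroring the nonautonomous, truncated
IGS copies seen in real spacers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import AnnotationBlock, Interval, SequenceRecord, reverse_complement

__all__ = [
    "SatelliteSpec",
    "SpeciesProfile",
    "ReadSimParams",
    "ReadTruth",
    "TruthSet",
    "build_landscape",
    "simulate_reads",
    "load_profile",
    "ONT_PROFILE",
    "HIFI_PROFILE",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_MAX_GENOME = 100_000_000  # practical bound on a simulated locus


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


@dataclass
class SatelliteSpec:
    """A satellite family planted in the IGS.

    ``copies_range`` is the per-unit copy number, drawn uniformly (the study
    species show strong array-length variation between units but no stated
    distribution). ``monomer_len_range`` lets individual copies vary in
    length (by 3'-truncation), as in AuSat-like satellites.
    """

    monomer_len: int
    copies_range: tuple[int, int]
    monomer_len_range: tuple[int, int] | None = None
    monomer_seq: str | None = None
    copy_divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.monomer_len < 10:
            raise ValueError("monomer_len must be >= 10")
        lo, hi = self.copies_range
        if not (0 < lo <= hi):
            raise ValueError("empty copies_range")


@dataclass
class SpeciesProfile:
    name: str
    gene_lengths: dict[str, int]
    igs_elements: list[tuple[str, int]] = field(default_factory=list)
    satellite: SatelliteSpec | None = None
    microsatellites: list[tuple[str, int]] = field(default_factory=list)
    r2_insertion_fraction: float = 0.0
    r2_length: int = 3000
    r2_label: str = "R2"
    n_units: int = 10
    unit_divergence: float = 0.002
    igs_spacer_len: int = 300
    flank_len: int = 5000
    telomere_flank: bool = False
    irregular_fraction: float = 0.0  # units with a shuffled IGS element order

    def __post_init__(self) -> None:
        if not (0 <= self.r2_insertion_fraction <= 1):
            raise ValueError("r2_insertion_fraction outside [0, 1]")
        for label, length in list(self.gene_lengths.items()) + self.igs_elements:
            if length <= 0:
                raise ValueError(f"non-positive length for {label}")


@dataclass
class ReadSimParams:
    """Read simulation settings.

    Long mode draws log-normal read lengths (given median and sigma of the
    log); paired mode emits mates of ``read_len`` from fragments of
    ``insert_size``. ``error_rate`` is the total per-base error rate, split
    into substitution/insertion/deletion parts by ``error_split``. Default
    long-read presets: ONT-like median 8 kb at 7% error, HiFi-like median
    15 kb at 0.3% error.
    """

    mode: str = "long"  # {long, paired}
    n_reads: int | None = None
    coverage: float | None = None
    median_len: int = 8000
    sigma: float = 0.35
    max_len: int | None = None  # hard cap on drawn read lengths
    read_len: int = 150
    insert_size: int = 450
    error_rate: float = 0.0
    error_split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    mean_q: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("long", "paired"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate outside [0, 1)")
        if abs(sum(self.error_split) - 1) > 1e-9:
            raise ValueError("error_split must sum to 1")


ONT_PROFILE = ReadSimParams(mode="long", median_len=8000, error_rate=0.07, mean_q=12)
HIFI_PROFILE = ReadSimParams(mode="long", median_len=15000, error_rate=0.003, mean_q=30)


@dataclass
class ReadTruth:
    read_id: str
    origin: Interval  # on the landscape genome, plus-strand coordinates
    strand: str
    unit_index: int | None = None  # unit containing the read midpoint

    def to_json(self) -> dict:
        return {
            "read_id": self.read_id,
            "start": self.origin.start,
            "end": self.origin.end,
            "strand": self.strand,
            "unit_index": self.unit_index,
        }


@dataclass
class TruthSet:
    genome: SequenceRecord
    blocks: list[AnnotationBlock]
    unit_bounds: list[tuple[int, int]]
    gene_refs: dict[str, str]
    repeat_library: dict[str, str]  # full-length element/satellite consensi
    r2_units: list[int]
    irregular_units: list[int]
    profile: SpeciesProfile

    def blocks_overlapping(self, start: int, end: int) -> list[AnnotationBlock]:
        return [b for b in self.blocks if b.start < end and b.end > start]

    def gene_bp_in(self, start: int, end: int) -> int:
        """Truth bp of rDNA transcription-unit labels within [start, end)."""
        genes = set(self.gene_refs)
        return sum(
            min(b.end, end) - max(b.start, start)
            for b in self.blocks_overlapping(start, end)
            if b.label in genes
        )


def _element_consensus(rng: np.random.Generator, length: int) -> str:
    return _random_seq(rng, length)


def _build_satellite_array(
    rng: np.random.Generator, spec: SatelliteSpec, monomer: str, n_copies: int
) -> str:
    lo, hi = spec.monomer_len_range or (spec.monomer_len, spec.monomer_len)
    parts = []
    for _ in range(n_copies):
        copy = _mutate(rng, monomer, spec.copy_divergence)
        if hi > lo:
            copy = copy[: int(rng.integers(lo, hi + 1))]
        parts.append(copy)
    return "".join(parts)


def _msat_array(motif: str, length: int) -> str:
    reps = math.ceil(length / len(motif))
    return (motif * reps)[:length]


def build_landscape(profile: SpeciesProfile, seed: int = 0) -> TruthSet:
    """Assemble a tandem rDNA locus with truth annotation.

    Exactly ``round(f * n_units)`` units carry the R2-type insertion inside
    28S and exactly ``round(irregular_fraction * n_units)`` units have their
    IGS element order shuffled; both unit sets are chosen uniformly.
    """
    rng = np.random.default_rng(seed)
    genes = {label: _random_seq(rng, n) for label, n in profile.gene_lengths.items()}

    # full-length consensi; the planted copy is a truncated fragment
    library: dict[str, str] = {}
    fragments: dict[str, str] = {}
    for i, (label, frag_len) in enumerate(profile.igs_elements):
        full = _element_consensus(rng, int(round(frag_len * 1.7)))
        library[label] = full
        # alternate 5'/3' truncation across elements
        fragments[label] = full[-frag_len:] if i % 2 else full[:frag_len]

    r2_seq = None
    if profile.r2_insertion_fraction > 0:
        r2_seq = _element_consensus(rng, profile.r2_length)
        library[profile.r2_label] = r2_seq

    monomer = None
    if profile.satellite is not None:
        monomer = profile.satellite.monomer_seq or _random_seq(
            rng, profile.satellite.monomer_len
        )
        library["satellite"] = monomer

    # IGS spacer templates, one per slot, shared across units: spacer DNA is
    # homologous between unit copies (it diverges like the rest of the unit)
    n_slots = (
        1
        + len(profile.igs_elements)
        + (1 if profile.satellite is not None else 0)
        + len(profile.microsatellites)
    )
    spacer_templates = [
        _random_seq(rng, profile.igs_spacer_len) for _ in range(n_slots)
    ]

    n_r2 = round(profile.r2_insertion_fraction * profile.n_units)
    r2_units = sorted(rng.choice(profile.n_units, size=n_r2, replace=False).tolist())
    n_irr = round(profile.irregular_fraction * profile.n_units)
    irregular_units = sorted(
        rng.choice(profile.n_units, size=n_irr, replace=False).tolist()
    )

    genome_id = f"{profile.name}_locus"
    parts: list[str] = []
    blocks: list[AnnotationBlock] = []
    unit_bounds: list[tuple[int, int]] = []
    pos = 0

    def emit(label: str, seq: str, source: str = "truth") -> None:
        nonlocal pos
        if not seq:
            return
        blocks.append(
            AnnotationBlock(label, Interval(genome_id, pos, pos + len(seq)), source)
        )
        parts.append(seq)
        pos += len(seq)

    flank = _random_seq(rng, profile.flank_len)
    if profile.telomere_flank:
        flank = _msat_array("TTAGG", 300) + flank[300:]
    parts.append(flank)
    pos += len(flank)

    for u in range(profile.n_units):
        unit_start = pos
        div = profile.unit_divergence
        for label in ("18S", "ITS1", "5.8S", "ITS2"):
            emit(label, _mutate(rng, genes[label], div))
        s28 = _mutate(rng, genes["28S"], div)
        if u in r2_units:
            site = int(0.65 * len(s28))  # R2 is site-specific within 28S
            emit("28S", s28[:site])
            emit(profile.r2_label, _mutate(rng, r2_seq, div))
            emit("28S", s28[site:])
        else:
            emit("28S", s28)
        # IGS: elements interleaved with anonymous spacer, then satellite(s)
        order = list(range(len(profile.igs_elements)))
        if u in irregular_units and len(order) > 1:
            while True:
                perm = rng.permutation(len(order)).tolist()
                if perm != order:
                    break
            order = perm
        slot = 0
        emit("IGS", _mutate(rng, spacer_templates[slot], div))
        for idx in order:
            label, _ = profile.igs_elements[idx]
            emit(label, _mutate(rng, fragments[label], div))
            slot += 1
            emit("IGS", _mutate(rng, spacer_templates[slot], div))
        if profile.satellite is not None:
            lo, hi = profile.satellite.copies_range
            n_copies = int(rng.integers(lo, hi + 1))
            emit(
                "satellite",
                _build_satellite_array(rng, profile.satellite, monomer, n_copies),
            )
            slot += 1
            emit("IGS", _mutate(rng, spacer_templates[slot], div))
        for motif, length in profile.microsatellites:
            emit(f"msat_{motif}", _msat_array(motif, length))
            slot += 1
            emit("IGS", _mutate(rng, spacer_templates[slot], div))
        unit_bounds.append((unit_start, pos))

    parts.append(_random_seq(rng, profile.flank_len))
    pos += profile.flank_len

    if pos > _MAX_GENOME:
        raise ValueError(f"simulated locus of {pos} bp exceeds {_MAX_GENOME} bp")

    genome = SequenceRecord(genome_id, "".join(parts))
    return TruthSet(
        genome=genome,
        blocks=blocks,
        unit_bounds=unit_bounds,
        gene_refs=genes,
        repeat_library=library,
        r2_units=r2_units,
        irregular_units=irregular_units,
        profile=profile,
    )


def _apply_errors(
    rng: np.random.Generator, seq: str, params: ReadSimParams
) -> str:
    e = params.error_rate
    if e <= 0:
        return seq
    p_sub, p_ins, p_del = params.error_split
    arr = list(seq)
    n = len(arr)
    n_sub = rng.binomial(n, e * p_sub)
    for i in rng.choice(n, size=min(n_sub, n), replace=False):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    n_del = rng.binomial(n, e * p_del)
    for i in sorted(rng.choice(n, size=min(n_del, n), replace=False), reverse=True):
        arr[i] = ""
    n_ins = rng.binomial(n, e * p_ins)
    for i in sorted(rng.choice(n, size=min(n_ins, n), replace=False), reverse=True):
        arr[i] = arr[i] + "ACGT"[rng.integers(4)]
    return "".join(arr)


def _qualities(rng: np.random.Generator, n: int, mean_q: float) -> list[int]:
    # constant target with +/-1 jitter keeps the probability-space mean
    # within one Phred unit of the target
    return (int(round(mean_q)) + rng.integers(-1, 2, size=n)).tolist()


def simulate_reads(
    truth: TruthSet, params: ReadSimParams, seed: int = 0
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Draw reads uniformly from the landscape genome (no chimeras).

    Returns the reads together with per-read truth (origin interval and
    strand on the landscape). With zero error rate each read is an exact
    substring of the genome or its reverse complement.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome.residues
    g_len = len(genome)

    if params.mode == "paired":
        return _simulate_paired(rng, truth, params)

    if params.n_reads is not None:
        n_reads = params.n_reads
    elif params.coverage is not None:
        n_reads = int(round(params.coverage * g_len / params.median_len))
    else:
        raise ValueError("need n_reads or coverage")
    if n_reads == 0:
        return [], []

    reads: list[SequenceRecord] = []
    truths: list[ReadTruth] = []
    for i in range(n_reads):
        length = int(rng.lognormal(math.log(params.median_len), params.sigma))
        if params.max_len is not None:
            length = min(length, params.max_len)
        length = max(200, min(length, g_len))
        start = int(rng.integers(0, g_len - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = genome[start : start + length]
        if strand == "-":
            template = reverse_complement(template)
        observed = _apply_errors(rng, template, params)
        rid = f"{truth.genome.id}_read{i:05d}"
        reads.append(
            SequenceRecord(rid, observed, _qualities(rng, len(observed), params.mean_q))
        )
        mid = start + length // 2
        unit = next(
            (k for k, (a, b) in enumerate(truth.unit_bounds) if a <= mid < b), None
        )
        truths.append(
            ReadTruth(rid, Interval(truth.genome.id, start, start + length), strand, unit)
        )
    return reads, truths


def _simulate_paired(
    rng: np.random.Generator, truth: TruthSet, params: ReadSimParams
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    genome = truth.genome.residues
    g_len = len(genome)
    insert = params.insert_size
    if params.n_reads is not None:
        n_pairs = params.n_reads
    elif params.coverage is not None:
        n_pairs = int(round(params.coverage * g_len / (2 * params.read_len)))
    else:
        raise ValueError("need n_reads or coverage")
    reads: list[SequenceRecord] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        start = int(rng.integers(0, max(1, g_len - insert + 1)))
        frag = genome[start : start + insert]
        r1 = frag[: params.read_len]
        r2 = reverse_complement(frag[-params.read_len :])
        for mate, seq in (("1", r1), ("2", r2)):
            observed = _apply_errors(rng, seq, params)
            rid = f"{truth.genome.id}_pair{i:06d}/{mate}"
            reads.append(
                SequenceRecord(
                    rid, observed, _qualities(rng, len(observed), params.mean_q)
                )
            )
            truths.append(
                ReadTruth(
                    rid,
                    Interval(truth.genome.id, start, start + insert),
                    "+" if mate == "1" else "-",
                )
            )
    return reads, truths


def unit_consensus(
    truth: TruthSet, unit_index: int | None = None
) -> tuple[SequenceRecord, list[AnnotationBlock]]:
    """One unit of the landscape as a consensus with unit-relative blocks.

    By default picks an R2-bearing unit if any exists (the coverage figures
    use a consensus that includes the insertion as an annotation block),
    else the first unit.
    """
    if unit_index is None:
        unit_index = truth.r2_units[0] if truth.r2_units else 0
    start, end = truth.unit_bounds[unit_index]
    cons_id = f"{truth.genome.id}_unit{unit_index}"
    seq = truth.genome.residues[start:end]
    blocks = [
        AnnotationBlock(
            b.label,
            Interval(cons_id, b.start - start, b.end - start, b.interval.strand),
            "truth",
        )
        for b in truth.blocks
        if b.start >= start and b.end <= end
    ]
    return SequenceRecord(cons_id, seq), blocks


def load_profile(path: str | Path) -> SpeciesProfile:
    """Load a species profile from the documented YAML schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sat = raw.pop("satellite", None)
    if sat is not None:
        sat = SatelliteSpec(
            monomer_len=sat["monomer_len"],
            copies_range=tuple(sat["copies_range"]),
            monomer_len_range=(
                tuple(sat["monomer_len_range"]) if "monomer_len_range" in sat else None
            ),
            monomer_seq=sat.get("monomer_seq"),
            copy_divergence=sat.get("copy_divergence", 0.02),
        )
    raw["igs_elements"] = [tuple(x) for x in raw.get("igs_elements", [])]
    raw["microsatellites"] = [tuple(x) for x in raw.get("microsatellites", [])]
    return SpeciesProfile(satellite=sat, **raw)


def builtin_profile(name: str) -> SpeciesProfile:
    """Load one of the shipped species presets by name."""
    path = Path(__file__).parent / "profiles" / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in path.parent.glob("*.yaml"))
        raise FileNotFoundError(f"no preset {name!r}; available: {available}")
    return load_profile(path)
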