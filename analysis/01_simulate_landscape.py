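#!/usr/bin/env python
"""Simulate the ghost-moth-like rDNA landscape and its long-read run.

Builds a tandem array of rDNA units whose IGS carries eight mobile-element
fragments, draws error-free unit-scale long reads, and writes genome, reads,
references and truth annotation under results/landscape/. Downstream
drivers (02, 03) consume these files.
"""

import argparse
from pathlib import Path

from rdnascope import seqio
from rdnascope.core import SequenceRecord
from rdnascope.simulate import (
    ReadSimParams,
    build_landscape,
    builtin_profile,
    simulate_reads,
)
import json

OUT = Path(__file__).resolve().parent.parent / "results" / "landscape"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-reads", type=int, default=200)
    args = ap.parse_args()

    profile = builtin_profile("hepialus_humuli")
    truth = build_landscape(profile, args.seed)
    unit_len = truth.unit_bounds[0][1] - truth.unit_bounds[0][0]
    params = ReadSimParams(
        mode="long", n_reads=args.n_reads, median_len=20_000, sigma=0.10,
        max_len=unit_len - 200, error_rate=0.0, mean_q=20,
    )
    reads, read_truth = simulate_reads(truth, params, args.seed + 1)

    OUT.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta([truth.genome], OUT / "genome.fasta")
    seqio.write_fastq(reads, OUT / "reads.fastq.gz")
    seqio.write_bed(truth.blocks, OUT / "truth.bed")
    seqio.write_fasta(
        [SequenceRecord(k, v) for k, v in truth.gene_refs.items()],
        OUT / "genes.fasta",
    )
    library = dict(truth.repeat_library)
    library.update(truth.gene_refs)
    seqio.write_fasta(
        [SequenceRecord(k, v) for k, v in library.items()], OUT / "library.fasta"
    )
    (OUT / "read_truth.json").write_text(
        json.dumps([t.to_json() for t in read_truth], indent=1)
    )

    print(f"landscape: {len(truth.genome):,} bp, {profile.n_units} units "
          f"of ~{unit_len:,} bp")
    print(f"IGS elements per unit: {[l for l, _ in profile.igs_elements]}")
    print(f"simulated {len(reads)} error-free long reads -> {OUT}")


if __name__ == "__main__":
    main()
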