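#!/usr/bin/env python
"""Generate the default two-event integration scenario.

Writes the host genome (two contigs, 200 kb + 120 kb at 36% GC), the
12.5 kb vector, the mutant haplotype carrying both integrations, ~29x
paired short reads (100 bp, 400+/-40 bp inserts, 0.5% substitutions) and
~30x long reads (~8 kb lognormal, ~8% mixed errors) from the mutant, plus
the ground-truth event files, under results/simulated/.
"""

import argparse
import sys
from pathlib import Path

from tdnascout import simgen
from tdnascout.io_formats import write_fasta, write_fastq

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    outdir = RESULTS / "simulated"
    outdir.mkdir(parents=True, exist_ok=True)

    fx = simgen.two_event_fixture(seed=args.seed)
    write_fasta(fx.genome, outdir / "genome.fa")
    write_fasta([fx.vector], outdir / "vector.fa")
    write_fasta(fx.mutant, outdir / "mutant_haplotype.fa")
    simgen.emit_truth(fx.events, outdir / "truth")

    sp = simgen.ShortReadParams(depth=29.0, seed=args.seed + 2)
    r1, r2 = simgen.simulate_short_reads(fx.mutant, sp)
    write_fastq(r1, outdir / "short_R1.fastq")
    write_fastq(r2, outdir / "short_R2.fastq")
    lp = simgen.LongReadParams(depth=30.0, seed=args.seed + 3)
    long_reads = simgen.simulate_long_reads(fx.mutant, lp)
    write_fastq(long_reads, outdir / "long.fastq")

    mean_len = sum(len(r.sequence) for r in long_reads) / len(long_reads)
    print(f"genome: {[len(c) for c in fx.genome]} bp, vector {len(fx.vector)} bp")
    for e in fx.events:
        print(
            f"  {e.label}: {e.chrom} deletion {e.del_start}-{e.del_end} "
            f"({e.del_len} bp) replaced by vector {e.v_start}-{e.v_end} "
            f"({e.v_len} bp, orientation {e.orientation})"
        )
    print(f"short reads: {len(r1)} pairs; long reads: {len(long_reads)} "
          f"(mean {mean_len:.0f} bp)")
    print(f"wrote inputs and truth to {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
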