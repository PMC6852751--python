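#!/usr/bin/env python
"""Map the simulated reads against the composite reference and summarize QC.

The composite reference is the host genome plus the vector as an extra
contig, so chimeric fragments show up as vector/genome discordant pairs and
soft-clipped junction reads. Writes short.sam, long.sam and qc_summary.tsv
under results/alignments/.
"""

import argparse
import sys
from pathlib import Path

from tdnascout import junctions, litemap
from tdnascout.io_formats import SeqRecord, read_fasta, read_fastq, write_sam
from tdnascout.pipeline import VECTOR_NAME

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    indir = RESULTS / "simulated"
    if not (indir / "genome.fa").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    outdir = RESULTS / "alignments"
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(indir / "genome.fa")
    vector = SeqRecord(VECTOR_NAME, read_fasta(indir / "vector.fa")[0].sequence)
    composite = genome + [vector]
    header = [(c.id, len(c)) for c in composite]

    sparams = litemap.MapParams()
    index = litemap.build_index(composite, sparams)
    r1 = read_fastq(indir / "short_R1.fastq")
    r2 = read_fastq(indir / "short_R2.fastq")
    short_alns = []
    for a, b in zip(r1, r2):
        pid = a.id[:-2]
        short_alns.extend(
            litemap.map_paired(a.sequence, b.sequence, index, composite, sparams, read_id=pid)
        )
    write_sam(short_alns, header, outdir / "short.sam")

    lparams = litemap.MapParams.long_read()
    lindex = litemap.build_index(composite, lparams)
    long_reads = read_fastq(indir / "long.fastq")
    long_alns = [
        litemap.map_read(r.sequence, lindex, composite, lparams, read_id=r.id)[0]
        for r in long_reads
    ]
    write_sam(long_alns, header, outdir / "long.sam")

    qc_rows = [
        ("short", junctions.qc_summary(short_alns, r1 + r2, composite)),
        ("long", junctions.qc_summary(long_alns, long_reads, composite)),
    ]
    with open(outdir / "qc_summary.tsv", "w") as fh:
        fh.write("read_set\tmapped_fraction\tmean_depth\tq30_fraction\tmean_read_len\n")
        for name, qc in qc_rows:
            fh.write(
                f"{name}\t{qc['mapped_fraction']:.4f}\t{qc['mean_depth']:.2f}\t"
                f"{qc['q30_fraction']:.4f}\t{qc['mean_read_len']:.1f}\n"
            )
            print(
                f"{name} reads: {100*qc['mapped_fraction']:.2f}% mapped, "
                f"{qc['mean_depth']:.1f}x depth, mean length {qc['mean_read_len']:.0f} bp"
            )
    print(f"wrote alignments and QC to {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
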