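#!/usr/bin/env python
"""Run the integration-site detection chain on the simulated data and
compare the calls against the simulation truth.

Uses the files from 01 and the precomputed alignments from 02: screens
discordant pairs and vector-mapping soft clips, clusters suspicious sites,
extracts and polishes overlapping long reads, drops those without vector
sequence, and resolves the survivors into event calls. Writes the run report
under results/detection/ and a call-vs-truth table.
"""

import argparse
import logging
import sys
from pathlib import Path

from tdnascout import pipeline
from tdnascout.io_formats import read_events_json

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    sim = RESULTS / "simulated"
    aln = RESULTS / "alignments"
    if not (sim / "genome.fa").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    outdir = RESULTS / "detection"

    cfg = pipeline.PipelineConfig(
        output_dir=str(outdir),
        simulate=False,
        genome_fa=str(sim / "genome.fa"),
        vector_fa=str(sim / "vector.fa"),
        short_r1=str(sim / "short_R1.fastq"),
        short_r2=str(sim / "short_R2.fastq"),
        long_fq=str(sim / "long.fastq"),
        short_sam=str(aln / "short.sam") if (aln / "short.sam").exists() else None,
        long_sam=str(aln / "long.sam") if (aln / "long.sam").exists() else None,
    )
    report = pipeline.run_pipeline(cfg)

    truth = {e.chrom: e for e in read_events_json(sim / "truth.json")}
    rows = []
    for call in report.calls:
        if call["status"] != "confirmed":
            continue
        t = truth.get(call["chrom"])
        rows.append((
            call["label"], call["chrom"],
            call["del_start"], call["del_end"], call["v_start"], call["v_end"],
            call["orientation"],
            call["del_start"] - t.del_start if t else "",
            call["del_end"] - t.del_end if t else "",
        ))
    with open(outdir / "calls_vs_truth.tsv", "w") as fh:
        fh.write("label\tchrom\tdel_start\tdel_end\tv_start\tv_end\t"
                 "orientation\tdel_start_err\tdel_end_err\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
            print("call:", row)
    n_exact = sum(1 for r in rows if r[-1] == 0 and r[-2] == 0)
    print(f"{len(rows)} confirmed calls, {n_exact} with exact deletion breakpoints")
    print(f"report under {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
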