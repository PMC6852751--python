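#!/usr/bin/env python
"""Junction PCR verification in silico.

For each confirmed event, designs a primer pair spanning the left junction
(forward primer on the genomic flank, reverse primer inside the inserted
vector fragment) and predicts products on the wild-type and mutant
haplotypes: diagnostic pairs amplify from the mutant only, mirroring gel
verification of insertion borders. Writes results/pcr/junction_pcr.tsv.
"""

import argparse
import sys
from pathlib import Path

from tdnascout.insilico_pcr import PrimerPair, genotype_event
from tdnascout.io_formats import read_events_json, read_fasta, revcomp

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    sim = RESULTS / "simulated"
    if not (sim / "truth.json").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    outdir = RESULTS / "pcr"
    outdir.mkdir(parents=True, exist_ok=True)

    genome = {c.id: c.sequence for c in read_fasta(sim / "genome.fa")}
    mutant = {c.id: c.sequence for c in read_fasta(sim / "mutant_haplotype.fa")}
    vector = read_fasta(sim / "vector.fa")[0].sequence
    events = read_events_json(sim / "truth.json")

    rows = []
    for e in events:
        g = genome[e.chrom]
        fwd = g[e.del_start - 121 : e.del_start - 101]  # genomic left flank
        frag = vector[e.v_start - 1 : e.v_end]
        ins = frag if e.orientation == "+" else revcomp(frag)
        rev = revcomp(ins[80:100])  # inside the inserted fragment
        pair = PrimerPair(f"{e.label}_LB", fwd, rev)
        res = genotype_event(pair, genome, mutant)
        wt_lens = [a.length for a in res["wt"]] or ["-"]
        mut_lens = [a.length for a in res["mutant"]] or ["-"]
        rows.append((pair.name, e.chrom, wt_lens, mut_lens, res["diagnostic"]))
        print(
            f"{pair.name}: wild type {wt_lens}, mutant {mut_lens} bp "
            f"-> diagnostic={res['diagnostic']}"
        )

    with open(outdir / "junction_pcr.tsv", "w") as fh:
        fh.write("pair\tchrom\twt_products\tmutant_products\tdiagnostic\n")
        for name, chrom, wt, mut, diag in rows:
            fh.write(f"{name}\t{chrom}\t{','.join(map(str, wt))}\t"
                     f"{','.join(map(str, mut))}\t{diag}\n")
    print(f"wrote {outdir / 'junction_pcr.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
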