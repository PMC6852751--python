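#!/usr/bin/env python
"""Feature impact of the deletions.

Two parts: (a) the published Chr5 case — a 371 bp deletion over a gene
whose 5'UTR ends at 1,729,114 and whose CDS starts at 1,729,115 — is
decomposed into per-feature base pairs lost; (b) the confirmed calls from
03 are intersected with a synthetic gene model planted over the contig1
event. Writes results/annotation/feature_impact.tsv.
"""

import argparse
import json
import sys
from pathlib import Path

from tdnascout.annotate import overlap_deletion
from tdnascout.io_formats import EventRecord, GffFeature

RESULTS = Path(__file__).resolve().parents[1] / "results"


def chr5_case():
    features = [
        GffFeature("Chr5", "gene", 1_728_000, 1_732_000, "+", {"ID": "BpCOI1"}),
        GffFeature("Chr5", "five_prime_UTR", 1_729_008, 1_729_114, "+", {"Parent": "m"}),
        GffFeature("Chr5", "exon", 1_729_008, 1_729_600, "+", {"Parent": "m"}),
        GffFeature("Chr5", "CDS", 1_729_115, 1_729_600, "+", {"Parent": "m"}),
    ]
    event = EventRecord("Chr5", 1_729_008, 1_729_378, 10_719, 11_106, "+", "chr5")
    return overlap_deletion(event, features)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    outdir = RESULTS / "annotation"
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    ov = chr5_case()
    for ftype, bp in ov.bp_by_type.items():
        if bp:
            rows.append(("chr5_published", "BpCOI1", ftype, bp))
    print(f"published Chr5 deletion: {ov.describe()}")

    calls_path = RESULTS / "detection" / "calls.json"
    if calls_path.exists():
        report = json.loads(calls_path.read_text())
        truth_like = [c for c in report["calls"] if c["status"] == "confirmed"]
        for call in truth_like:
            if call["chrom"] != "contig1":
                rows.append((call["label"], "-", "no known gene", call["del_len"]))
                continue
            # synthetic annotation: a gene whose 5'UTR covers the first 107
            # deleted bases and whose CDS starts right after, mirroring the
            # disrupted-gene geometry
            ds = call["del_start"]
            feats = [
                GffFeature("contig1", "gene", ds - 1000, ds + 2000, "+", {"ID": "gene_c1"}),
                GffFeature("contig1", "five_prime_UTR", ds - 200, ds + 106, "+", {}),
                GffFeature("contig1", "exon", ds - 200, ds + 2000, "+", {}),
                GffFeature("contig1", "CDS", ds + 107, ds + 2000, "+", {}),
            ]
            ev = EventRecord(
                call["chrom"], call["del_start"], call["del_end"],
                call["v_start"], call["v_end"], call["orientation"], call["label"],
            )
            ovc = overlap_deletion(ev, feats)
            print(f"{call['label']}: {ovc.describe()}")
            for ftype, bp in ovc.bp_by_type.items():
                if bp:
                    rows.append((call["label"], "gene_c1", ftype, bp))
    else:
        print("no detection output found; run analysis/03_detect_insertions.py "
              "for the called-event section", file=sys.stderr)

    with open(outdir / "feature_impact.tsv", "w") as fh:
        fh.write("event\tgene\tfeature_type\tbp\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    print(f"wrote {outdir / 'feature_impact.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
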