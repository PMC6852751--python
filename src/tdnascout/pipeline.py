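"""Config-driven end-to-end runs: simulate -> map -> detect -> annotate ->
pcr -> report.

Every stage is importable on its own; this module wires them together,
echoes the per-stage evidence counts to the log (suspicious sites found,
target reads extracted, reads excluded for lacking vector sequence,
confirmed calls) and writes machine-readable outputs under ``output_dir``:
``calls.json``, ``deletions.bed``, ``evidence.tsv``, plus intermediate SAM
and corrected-read FASTA files for inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as annotate_mod
from . import insilico_pcr, junctions, litemap, simgen
from .io_formats import (
    AlnRecord,
    EventRecord,
    SeqRecord,
    read_fasta,
    read_fastq,
    read_gff3,
    read_sam,
    write_fasta,
    write_sam,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

VECTOR_NAME = "TDNA_vector"


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one run.

    Either ``simulate`` is True (inputs generated by simgen with the
    fixture geometry and ``seed``) or the four file paths must exist.
    """

    output_dir: str = "tdna_scout_out"
    seed: int = 1
    simulate: bool = True
    genome_fa: str | None = None
    vector_fa: str | None = None
    short_r1: str | None = None
    short_r2: str | None = None
    long_fq: str | None = None
    short_sam: str | None = None
    long_sam: str | None = None
    gff3: str | None = None
    primers_tsv: str | None = None
    # simulation block
    contig_lengths: tuple[int, ...] = (200_000, 120_000)
    gc: float = 0.36
    short_depth: float = 29.0
    short_sub_rate: float = 0.005
    long_depth: float = 30.0
    long_error: tuple[float, float, float] = (0.027, 0.027, 0.026)
    events: list[EventRecord] | None = None  # None => fixture defaults
    # detection block
    min_mapq: int = junctions.DEFAULT_MIN_MAPQ
    min_clip: int = junctions.DEFAULT_MIN_CLIP
    min_evidence: int = junctions.DEFAULT_MIN_EVIDENCE
    min_long_support: int = 1
    window: int | None = None  # None => insert_mean + 4*insert_sd
    flank: int = junctions.DEFAULT_FLANK
    containment_k: int = 21
    containment_min_hits: int = 5
    correction_k: int = 13
    correction_min_cov: int = 3
    insert_mean: int = 400
    insert_sd: int = 40
    read_len: int = 100

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        events = data.pop("events", None)
        cfg = cls(**data)
        if events is not None:
            cfg.events = [EventRecord(**e) for e in events]
        return cfg


@dataclass
class RunReport:
    counts: dict[str, float | int] = field(default_factory=dict)
    qc_short: dict[str, float] = field(default_factory=dict)
    qc_long: dict[str, float] = field(default_factory=dict)
    calls: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.events is None and len(cfg.contig_lengths) == 2:
        fx = simgen.two_event_fixture(
            seed=cfg.seed,
            contig1_len=cfg.contig_lengths[0],
            contig2_len=cfg.contig_lengths[1],
        )
        genome, vector, events, mutant = fx.genome, fx.vector, fx.events, fx.mutant
    else:
        genome = simgen.simulate_genome(
            len(cfg.contig_lengths), list(cfg.contig_lengths), cfg.gc, seed=cfg.seed
        )
        vector = simgen.simulate_vector(simgen.VectorSpec(), seed=cfg.seed + 1)
        events = cfg.events or []
        mutant, _ = simgen.apply_events(genome, vector, events)
    sp = simgen.ShortReadParams(
        read_len=cfg.read_len,
        insert_mean=cfg.insert_mean,
        insert_sd=cfg.insert_sd,
        depth=cfg.short_depth,
        sub_rate=cfg.short_sub_rate,
        seed=cfg.seed + 2,
    )
    r1, r2 = simgen.simulate_short_reads(mutant, sp)
    lp = simgen.LongReadParams(
        depth=cfg.long_depth,
        sub_rate=cfg.long_error[0],
        ins_rate=cfg.long_error[1],
        del_rate=cfg.long_error[2],
        seed=cfg.seed + 3,
    )
    long_reads = simgen.simulate_long_reads(mutant, lp)
    write_fasta(genome, outdir / "genome.fa")
    write_fasta([vector], outdir / "vector.fa")
    write_fasta(mutant, outdir / "mutant_haplotype.fa")
    simgen.emit_truth(events, outdir / "truth")
    return genome, vector, r1, r2, long_reads


def _group_pairs(alns: list[AlnRecord]) -> list[tuple[AlnRecord, AlnRecord]]:
    by_id: dict[str, list[AlnRecord]] = {}
    for a in alns:
        if not a.is_paired or a.secondary:
            continue
        by_id.setdefault(a.query_id.rsplit("/", 1)[0], []).append(a)
    return [(v[0], v[1]) for v in by_id.values() if len(v) == 2]


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: str(v) for k, v in dataclasses.asdict(cfg).items()})

    # ---- inputs
    if cfg.simulate:
        genome, vector, r1, r2, long_reads = _simulate_inputs(cfg, outdir)
    else:
        genome = read_fasta(cfg.genome_fa)
        vecs = read_fasta(cfg.vector_fa)
        if len(vecs) != 1:
            raise ValueError("vector FASTA must contain exactly one sequence")
        vector = SeqRecord(VECTOR_NAME, vecs[0].sequence)
        r1 = read_fastq(cfg.short_r1)
        r2 = read_fastq(cfg.short_r2)
        long_reads = read_fastq(cfg.long_fq)
    vector = SeqRecord(VECTOR_NAME, vector.sequence)
    composite = genome + [vector]
    header_refs = [(c.id, len(c)) for c in composite]
    logger.info(
        "inputs: %d genome contigs, vector %d bp, %d read pairs, %d long reads",
        len(genome), len(vector), len(r1), len(long_reads),
    )

    # ---- mapping
    sparams = litemap.MapParams(insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd)
    lparams = litemap.MapParams.long_read()
    if cfg.short_sam:
        short_alns = read_sam(cfg.short_sam)
        pairs = _group_pairs(short_alns)
    else:
        index = litemap.build_index(composite, sparams)
        pairs = []
        for a, b in zip(r1, r2):
            pid = a.id[:-2] if a.id.endswith(("/1", "/2")) else a.id
            pairs.append(
                litemap.map_paired(a.sequence, b.sequence, index, composite, sparams, read_id=pid)
            )
        short_alns = [rec for p in pairs for rec in p]
        write_sam(short_alns, header_refs, outdir / "short.sam")
    if cfg.long_sam:
        long_alns = read_sam(cfg.long_sam)
    else:
        lindex = litemap.build_index(composite, lparams)
        long_alns = [
            litemap.map_read(r.sequence, lindex, composite, lparams, read_id=r.id)[0]
            for r in long_reads
        ]
        write_sam(long_alns, header_refs, outdir / "long.sam")
    report.qc_short = junctions.qc_summary(short_alns, r1 + r2, composite)
    report.qc_long = junctions.qc_summary(long_alns, long_reads, composite)
    logger.info(
        "short reads: %.2f%% mapped, depth %.1fx; long reads: %.2f%% mapped, depth %.1fx",
        100 * report.qc_short["mapped_fraction"], report.qc_short["mean_depth"],
        100 * report.qc_long["mapped_fraction"], report.qc_long["mean_depth"],
    )

    # ---- screening and clustering
    ref_names = [c.id for c in composite]
    disc = junctions.screen_discordant(pairs, VECTOR_NAME, ref_names, min_mapq=cfg.min_mapq)
    sindex = litemap.build_index(composite, litemap.MapParams(k=13, min_chain_anchors=1))
    splits = junctions.screen_splits(
        short_alns, composite, sindex, VECTOR_NAME,
        min_clip=cfg.min_clip, min_mapq=cfg.min_mapq,
    )
    window = cfg.window or cfg.insert_mean + 4 * cfg.insert_sd
    sites = junctions.cluster_candidates(
        disc, splits, window=window, min_evidence=cfg.min_evidence
    )
    logger.info(
        "%d discordant pairs, %d split reads -> %d suspicious insertion sites",
        len(disc), len(splits), len(sites),
    )

    # ---- long-read confirmation
    genome_by_id = {c.id: c.sequence for c in genome}
    lr_by_id = {r.id: r for r in long_reads}
    target_ids = junctions.extract_target_longreads(long_alns, sites, flank=cfg.flank)
    targets = [lr_by_id[i] for i in sorted(target_ids)]
    logger.info("extracted %d target long reads at suspicious sites", len(targets))
    corrected = junctions.correct_longreads(
        targets, r1 + r2, k=cfg.correction_k, min_cov=cfg.correction_min_cov
    )
    for c in corrected:
        c.contains_tdna = junctions.tdna_containment(
            c.sequence, vector.sequence, k=cfg.containment_k,
            min_hits=cfg.containment_min_hits,
        )
    kept = [c for c in corrected if c.contains_tdna]
    n_excluded = len(corrected) - len(kept)
    logger.info(
        "%d corrected reads without T-DNA sequence excluded; %d retained",
        n_excluded, len(kept),
    )
    write_fasta(
        [SeqRecord(c.read_id.replace("/", "_"), c.sequence) for c in kept],
        outdir / "corrected_tdna_reads.fa",
    )

    # assign kept reads to sites through their genome alignment interval; a
    # read whose primary landed on the vector contig (mostly-vector junction
    # read) is offered to every site and self-selects via its genome anchors
    aln_by_id = {a.query_id: a for a in long_alns if not a.unmapped and not a.secondary}
    calls: list[junctions.EventCall] = []
    for i, site in enumerate(sites, start=1):
        site_reads = []
        for c in kept:
            a = aln_by_id.get(c.read_id)
            if a is None:
                continue
            if a.ref_id == VECTOR_NAME:
                site_reads.append(c)
            elif a.ref_id == site.chrom and (
                a.pos <= site.window_end + cfg.flank
                and a.ref_end() >= site.window_start - cfg.flank
            ):
                site_reads.append(c)
        call = junctions.resolve_breakpoints(
            site, site_reads, genome_by_id, vector.sequence,
            k=cfg.containment_k, flank=junctions.DEFAULT_RESOLVE_FLANK,
        )
        call.label = f"site{i}"
        if call.support["long_reads"] < cfg.min_long_support:
            call.status = "candidate" if call.status == "confirmed" else call.status
        calls.append(call)
    calls = junctions.merge_one_sided_calls(calls)
    for i, call in enumerate(calls, start=1):
        call.label = f"event{i}"
    confirmed = [c for c in calls if c.status == "confirmed"]
    logger.info("%d sites resolved as confirmed T-DNA insertion events", len(confirmed))

    # ---- annotation and in-silico PCR
    overlaps = {}
    if cfg.gff3:
        features = read_gff3(cfg.gff3)
        for call in confirmed:
            ev = EventRecord(
                chrom=call.chrom, del_start=call.del_start, del_end=call.del_end,
                v_start=call.v_start or 1, v_end=call.v_end or 1,
                orientation=call.orientation or "+", label=call.label,
            )
            overlaps[call.label] = annotate_mod.overlap_deletion(ev, features)
    pcr_results = {}
    if cfg.primers_tsv:
        import pandas as pd

        mutant_map = None
        if cfg.simulate:
            mutant_map = {
                c.id: c.sequence for c in read_fasta(outdir / "mutant_haplotype.fa")
            }
        wt_map = {c.id: c.sequence for c in genome}
        wt_map[VECTOR_NAME] = ""  # vector absent from wild type
        df = pd.read_csv(cfg.primers_tsv, sep="\t")
        for _, row in df.iterrows():
            pair = insilico_pcr.PrimerPair(row["name"], row["fwd"], row["rev"])
            if mutant_map is not None:
                pcr_results[pair.name] = insilico_pcr.genotype_event(
                    pair, {k: v for k, v in wt_map.items() if v}, mutant_map
                )

    # ---- report
    report.counts = {
        "read_pairs": len(r1),
        "long_reads": len(long_reads),
        "discordant_pairs": len(disc),
        "split_reads": len(splits),
        "suspicious_sites": len(sites),
        "target_long_reads": len(targets),
        "excluded_no_tdna": n_excluded,
        "tdna_reads_kept": len(kept),
        "confirmed_calls": len(confirmed),
    }
    assert report.counts["excluded_no_tdna"] + report.counts["tdna_reads_kept"] == report.counts["target_long_reads"]
    for call in calls:
        entry = dataclasses.asdict(call)
        entry["del_len"] = call.del_len
        entry["v_len"] = call.v_len
        if call.label in overlaps:
            entry["feature_overlap"] = dataclasses.asdict(overlaps[call.label])
        report.calls.append(entry)
    (outdir / "calls.json").write_text(report.to_json() + "\n")
    _write_bed(confirmed, outdir / "deletions.bed")
    _write_evidence_tsv(sites, outdir / "evidence.tsv")
    if pcr_results:
        _write_pcr_tsv(pcr_results, outdir / "pcr.tsv")
    return report


def _write_bed(calls: list[junctions.EventCall], path: Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.del_start - 1}\t{c.del_end}\t{c.label}\t0\t{c.orientation or '.'}\n"
            )


def _write_evidence_tsv(sites: list[junctions.CandidateSite], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\twindow_end\tpair_support\tsplit_support\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.window_start}\t{s.window_end}\t{s.pair_support}\t{s.split_support}\n"
            )


def _write_pcr_tsv(results: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\ttemplate\tproduct_bp\tdiagnostic\n")
        for name in sorted(results):
            res = results[name]
            for label in ("wt", "mutant"):
                for amp in res[label]:
                    fh.write(
                        f"{name}\t{label}:{amp.template_id}\t{amp.length}\t{res['diagnostic']}\n"
                    )
            if not res["wt"] and not res["mutant"]:
                fh.write(f"{name}\t-\t0\t{res['diagnostic']}\n")
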