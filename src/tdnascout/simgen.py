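"""Synthetic re-sequencing data for a clonal transgenic line.

Generates a multi-contig host genome, a binary-vector sequence carrying a
marker cassette, 1-3 integration events in which a contiguous vector fragment
replaces a genomic interval, and short paired-end plus long single-molecule
reads from the resulting mutant haplotype. Read ids encode their true origin
so tests can use them as an exact oracle.

The default scenario (:func:`two_event_fixture`) plants two events whose
geometry mirrors the two classes of integration the detector must resolve: a
small vector fragment (388 bp) replacing a short interval (371 bp) inside a
gene, and a large fragment (8159 bp) replacing a ~49 kb interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    EventRecord,
    FastqRecord,
    SeqRecord,
    revcomp,
    write_events_bed,
    write_events_json,
)

__all__ = [
    "VectorSpec",
    "ShortReadParams",
    "LongReadParams",
    "CoordinateMap",
    "simulate_genome",
    "simulate_vector",
    "apply_events",
    "simulate_short_reads",
    "simulate_long_reads",
    "emit_truth",
    "two_event_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SHORT_READ_QUALITY = 30  # constant Phred for simulated short reads
LONG_READ_QUALITY = 12  # constant Phred for simulated long reads


@dataclass(frozen=True)
class VectorSpec:
    """Geometry of the binary vector: cassette and transgene intervals.

    Defaults mirror a pGWB2-style plasmid: ~12.5 kb total, an expression
    cassette spanning most of the T-DNA region and a 1089 bp transgene CDS
    inside it.
    """

    length: int = 12500
    cassette_start: int = 3967
    cassette_end: int = 12125
    transgene_start: int = 6000
    transgene_end: int = 7088
    lb_pos: int = 3800
    rb_pos: int = 12300

    def __post_init__(self) -> None:
        if not (
            1
            <= self.cassette_start
            <= self.transgene_start
            <= self.transgene_end
            <= self.cassette_end
            <= self.length
        ):
            raise ValueError("vector intervals must nest: cassette ⊇ transgene")

    @property
    def transgene_len(self) -> int:
        return self.transgene_end - self.transgene_start + 1


@dataclass(frozen=True)
class ShortReadParams:
    """Paired-end short-read model: uniform fragment start, Gaussian insert,
    per-base substitution errors, constant Q30."""

    read_len: int = 100
    insert_mean: int = 400
    insert_sd: int = 40
    depth: float = 29.0
    sub_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if self.insert_mean < 2 * self.read_len:
            raise ValueError("insert_mean must be >= 2*read_len")
        if not 0 <= self.sub_rate < 0.1:
            raise ValueError("sub_rate must be in [0, 0.1)")


@dataclass(frozen=True)
class LongReadParams:
    """Long-read model: lognormal lengths, mixed per-base sub/ins/del errors,
    constant Q12. Defaults target a ~8 kb mean read length at ~30x."""

    len_mean_log: float = 8.9629  # exp(mu + sigma^2/2) ~ 8055 bp at sigma=0.25
    len_sd_log: float = 0.25
    depth: float = 30.0
    sub_rate: float = 0.027
    ins_rate: float = 0.027
    del_rate: float = 0.026
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 0.15:
                raise ValueError("error rates must be in [0, 0.15)")

    @property
    def target_mean_len(self) -> float:
        return math.exp(self.len_mean_log + self.len_sd_log**2 / 2)


@dataclass
class CoordinateMap:
    """Lift-over between reference and mutant-haplotype coordinates.

    Per contig, stores the applied events sorted by position. A reference
    position outside every deleted interval maps to itself plus the cumulative
    length delta (v_len - del_len) of upstream events; deleted positions have
    no image and lift to None.
    """

    events_by_contig: dict[str, list[EventRecord]] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int) -> int | None:
        delta = 0
        for e in self.events_by_contig.get(chrom, []):
            if pos > e.del_end:
                delta += e.v_len - e.del_len
            elif pos >= e.del_start:
                return None  # deleted
        return pos + delta


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(
    n_contigs: int, lengths: list[int], gc: float, seed: int
) -> list[SeqRecord]:
    """Random host contigs with the requested GC content."""
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have n_contigs entries")
    if any(length < 1 for length in lengths):
        raise ValueError("contig lengths must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for i, length in enumerate(lengths, start=1):
        idx = rng.choice(4, size=length, p=p)
        seq = _BASES[idx].tobytes().decode()
        out.append(SeqRecord(f"contig{i}", seq))
    return out


def simulate_vector(spec: VectorSpec, seed: int) -> SeqRecord:
    """Random vector sequence of the specified geometry (linear; the
    integrated material is always a linear fragment of it)."""
    rng = _rng(seed)
    idx = rng.integers(0, 4, size=spec.length)
    return SeqRecord("TDNA_vector", _BASES[idx].tobytes().decode())


def apply_events(
    genome: list[SeqRecord],
    vector: SeqRecord,
    events: list[EventRecord],
) -> tuple[list[SeqRecord], CoordinateMap]:
    """Build the mutant haplotype by replacing each deletion interval with its
    vector fragment (reverse-complemented for orientation '-')."""
    by_contig: dict[str, list[EventRecord]] = {}
    contig_len = {c.id: len(c) for c in genome}
    for e in events:
        if e.chrom not in contig_len:
            raise ValueError(f"event {e.label}: contig {e.chrom} not in genome")
        if e.del_end > contig_len[e.chrom] or e.del_start < 1:
            raise ValueError(f"event {e.label}: coordinates outside {e.chrom}")
        if not 1 <= e.v_start <= e.v_end <= len(vector):
            raise ValueError(f"event {e.label}: vector interval outside vector")
        by_contig.setdefault(e.chrom, []).append(e)
    for chrom, evs in by_contig.items():
        evs.sort(key=lambda e: e.del_start)
        for a, b in zip(evs, evs[1:]):
            if b.del_start <= a.del_end:
                raise ValueError(f"overlapping events on {chrom}: {a.label}, {b.label}")

    mutant = []
    for contig in genome:
        evs = by_contig.get(contig.id, [])
        parts: list[str] = []
        cursor = 1
        for e in evs:
            parts.append(contig.sequence[cursor - 1 : e.del_start - 1])
            frag = vector.sequence[e.v_start - 1 : e.v_end]
            parts.append(frag if e.orientation == "+" else revcomp(frag))
            cursor = e.del_end + 1
        parts.append(contig.sequence[cursor - 1 :])
        mutant.append(SeqRecord(contig.id, "".join(parts)))
    return mutant, CoordinateMap(by_contig)


def _apply_substitutions(
    arr: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return arr
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # shift by 1-3 positions in base order => always a different base
        arr = arr.copy()
        base_idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(base_idx + rng.integers(1, 4, size=hits.size)) % 4]
    return arr


def simulate_short_reads(
    haplotype: list[SeqRecord], params: ShortReadParams
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Paired-end reads at the requested depth.

    Fragment count is ceil(depth * total_len / (2 * read_len)); fragments are
    apportioned to contigs by length. Read ids encode the true origin as
    ``sr<serial>/<contig>/<fragment-start>/<strand>`` where strand is the
    strand R1 was drawn from.
    """
    rng = _rng(params.seed)
    total_len = sum(len(c) for c in haplotype)
    n_frag = math.ceil(params.depth * total_len / (2 * params.read_len))
    for c in haplotype:
        if params.insert_mean > len(c):
            raise ValueError(f"insert_mean exceeds contig {c.id} length")
    quals = (SHORT_READ_QUALITY,) * params.read_len
    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    weights = np.array([len(c) for c in haplotype], dtype=float)
    contig_choice = rng.choice(len(haplotype), size=n_frag, p=weights / weights.sum())
    serial = 0
    for ci, contig in enumerate(haplotype):
        n_here = int((contig_choice == ci).sum())
        L = len(contig)
        arr = np.frombuffer(contig.sequence.encode(), dtype=np.uint8)
        sizes = np.clip(
            np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_here)),
            2 * params.read_len,
            L,
        ).astype(int)
        starts = rng.integers(1, L - sizes + 2)  # 1-based fragment start
        strands = rng.integers(0, 2, size=n_here)  # 0:'+' R1 at left end
        for size, start, sflag in zip(sizes, starts, strands):
            serial += 1
            frag = arr[start - 1 : start - 1 + size]
            left = frag[: params.read_len]
            right = frag[-params.read_len :]
            # FR library: R1 from one fragment strand, R2 from the other, so
            # the mates face each other; ids record the strand R1 came from.
            left_m = _apply_substitutions(left, params.sub_rate, rng).tobytes().decode()
            right_m = _apply_substitutions(right, params.sub_rate, rng).tobytes().decode()
            if sflag == 0:
                r1, r2, strand = left_m, revcomp(right_m), "+"
            else:
                r1, r2, strand = revcomp(right_m), left_m, "-"
            name = f"sr{serial}/{contig.id}/{start}/{strand}"
            r1_out.append(FastqRecord(name + "/1", r1, quals))
            r2_out.append(FastqRecord(name + "/2", r2, quals))
    return r1_out, r2_out


def _mutate_long(
    frag: str, params: LongReadParams, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(frag.encode(), dtype=np.uint8)
    arr = _apply_substitutions(arr, params.sub_rate, rng)
    if params.ins_rate <= 0 and params.del_rate <= 0:
        return arr.tobytes().decode()
    keep = rng.random(arr.size) >= params.del_rate
    ins = rng.random(arr.size) < params.ins_rate
    out = bytearray()
    ins_bases = _BASES[rng.integers(0, 4, size=int(ins.sum()))]
    j = 0
    for i in range(arr.size):
        if keep[i]:
            out.append(arr[i])
        if ins[i]:
            out.append(ins_bases[j])
            j += 1
    return out.decode()


def simulate_long_reads(
    haplotype: list[SeqRecord], params: LongReadParams
) -> list[FastqRecord]:
    """Single-molecule long reads with lognormal lengths and indel-rich
    errors. Ids encode ``lr<serial>/<contig>/<start>/<strand>`` where start is
    the 1-based leftmost spanned haplotype base."""
    rng = _rng(params.seed)
    total_len = sum(len(c) for c in haplotype)
    target_bases = params.depth * total_len
    weights = np.array([len(c) for c in haplotype], dtype=float)
    out: list[FastqRecord] = []
    emitted = 0
    serial = 0
    while emitted < target_bases:
        ci = int(rng.choice(len(haplotype), p=weights / weights.sum()))
        contig = haplotype[ci]
        L = len(contig)
        span = int(np.clip(round(rng.lognormal(params.len_mean_log, params.len_sd_log)), 500, L))
        start = int(rng.integers(1, L - span + 2))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        frag = contig.sequence[start - 1 : start - 1 + span]
        if strand == "-":
            frag = revcomp(frag)
        seq = _mutate_long(frag, params, rng)
        serial += 1
        out.append(
            FastqRecord(
                f"lr{serial}/{contig.id}/{start}/{strand}",
                seq,
                (LONG_READ_QUALITY,) * len(seq),
            )
        )
        emitted += span
    return out


def emit_truth(events: list[EventRecord], prefix: str | Path) -> tuple[Path, Path]:
    """Write the simulated events as JSON (full geometry) and BED (deletions)."""
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    bed_path = prefix.with_suffix(".bed")
    write_events_json(events, json_path)
    write_events_bed(events, bed_path)
    return json_path, bed_path


def _junction_identifiable(genome: str, vector: str, e: EventRecord) -> bool:
    """True when neither junction of the event carries chance single-base
    homology between flank and insert, so breakpoints are unambiguous.

    The event model does not include junction microhomology; random
    sequences can still produce it by accident, which would make the exact
    breakpoint unidentifiable from any read. Fixture placement rejects such
    positions.
    """
    if e.del_len <= 0:
        return True
    frag = vector[e.v_start - 1 : e.v_end]
    ins = frag if e.orientation == "+" else revcomp(frag)
    # bases just outside the inserted fragment on the vector, junction side
    if e.orientation == "+":
        before = vector[e.v_start - 2] if e.v_start > 1 else None
        after = vector[e.v_end] if e.v_end < len(vector) else None
    else:
        before = revcomp(vector[e.v_end]) if e.v_end < len(vector) else None
        after = revcomp(vector[e.v_start - 2]) if e.v_start > 1 else None
    first_del = genome[e.del_start - 1]
    last_flank = genome[e.del_start - 2] if e.del_start > 1 else None
    last_del = genome[e.del_end - 1]
    first_right = genome[e.del_end] if e.del_end < len(genome) else None
    ambiguous = (
        ins[0] == first_del  # left flank could claim the first insert base
        or (before is not None and before == last_flank)  # insert claims flank
        or ins[-1] == last_del  # right flank could claim the last insert base
        or (after is not None and after == first_right)
    )
    return not ambiguous


def _place_identifiable(
    genome: str, vector: str, e: EventRecord, max_shift: int = 50
) -> EventRecord:
    """Shift the deletion window by the smallest offset that makes both
    junctions identifiable; lengths and the vector interval are preserved."""
    for mag in range(max_shift + 1):
        for delta in ((mag,) if mag == 0 else (mag, -mag)):
            cand = replace(
                e, del_start=e.del_start + delta, del_end=e.del_end + delta
            )
            if _junction_identifiable(genome, vector, cand):
                return cand
    raise ValueError(f"no identifiable placement near {e.label}")


# ---------------------------------------------------------------- fixture


@dataclass(frozen=True)
class Fixture:
    """A complete simulated scenario: inputs plus ground truth."""

    genome: list[SeqRecord]
    vector: SeqRecord
    events: list[EventRecord]
    mutant: list[SeqRecord]
    coord_map: CoordinateMap
    vector_spec: VectorSpec


def two_event_fixture(
    seed: int = 20190417,
    contig1_len: int = 200_000,
    contig2_len: int = 120_000,
) -> Fixture:
    """The default two-event scenario.

    contig1 carries a small event (371 bp deletion replaced by a 388 bp
    vector fragment, forward orientation) at an interior position; contig2
    carries a large event (48,988 bp deletion replaced by the 8159 bp
    cassette fragment, reverse orientation).
    """
    genome = simulate_genome(2, [contig1_len, contig2_len], gc=0.36, seed=seed)
    spec = VectorSpec()
    vector = simulate_vector(spec, seed=seed + 1)
    nominal = [
        EventRecord(
            chrom="contig1",
            del_start=100_000,
            del_end=100_370,
            v_start=10_719,
            v_end=11_106,
            orientation="+",
            label="event_small",
        ),
        EventRecord(
            chrom="contig2",
            del_start=30_001,
            del_end=78_988,
            v_start=3_967,
            v_end=12_125,
            orientation="-",
            label="event_large",
        ),
    ]
    by_id = {c.id: c for c in genome}
    events = [
        _place_identifiable(by_id[e.chrom].sequence, vector.sequence, e)
        for e in nominal
    ]
    mutant, cmap = apply_events(genome, vector, events)
    return Fixture(genome, vector, events, mutant, cmap, spec)
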