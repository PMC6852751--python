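"""Readers and writers for the formats the pipeline touches.

Coordinates in every in-memory type and in JSON reports are 1-based inclusive;
BED output is the only 0-based half-open surface. FASTA/FASTQ IO is delegated
to Biopython, SAM IO to pysam and GFF3 parsing to gffutils, with the stricter
validation this pipeline relies on (unique ids, ACGTN alphabet, CIGAR/length
consistency) layered on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "SeqRecord",
    "FastqRecord",
    "AlnRecord",
    "GffFeature",
    "EventRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sam",
    "write_sam",
    "read_gff3",
    "read_events_json",
    "write_events_json",
    "read_events_bed",
    "write_events_bed",
    "revcomp",
]

_FASTA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violated the dialect this pipeline reads and writes."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastqRecord:
    """A read with per-base Phred qualities (0-93)."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )


@dataclass
class AlnRecord:
    """Minimal SAM-dialect alignment record.

    ``cigar`` is an ordered list of ``(op, length)`` with op in {M,I,D,S};
    soft clips may appear only at the ends. ``pos`` is the 1-based leftmost
    reference coordinate of the first aligned base.
    """

    query_id: str
    ref_id: str | None
    pos: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    mapq: int = 0
    is_paired: bool = False
    mate_ref_id: str | None = None
    mate_pos: int | None = None
    unmapped: bool = False
    secondary: bool = False
    proper_pair: bool = False
    seq: str | None = None

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def ref_span(self) -> int:
        """Reference bases consumed (M and D ops)."""
        return sum(n for op, n in self.cigar if op in "MD")

    def ref_end(self) -> int:
        """1-based inclusive rightmost aligned reference base."""
        return self.pos + self.ref_span() - 1

    def validate(self) -> "AlnRecord":
        if not self.unmapped:
            if self.pos < 1:
                raise FormatError(f"{self.query_id}: mapped record with pos {self.pos}")
            ops = [op for op, _ in self.cigar]
            for i, op in enumerate(ops):
                if op == "S" and 0 < i < len(ops) - 1:
                    raise FormatError(f"{self.query_id}: internal soft clip in CIGAR")
            if self.seq is not None and self.query_length() != len(self.seq):
                raise FormatError(
                    f"{self.query_id}: CIGAR consumes {self.query_length()} query "
                    f"bases but SEQ is {len(self.seq)} long"
                )
        return self


@dataclass(frozen=True)
class GffFeature:
    """One stranded GFF3 feature (gene/mRNA/exon/five_prime_UTR/CDS)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"feature {self.attributes.get('ID', '?')} on {self.seqid}: "
                f"end {self.end} < start {self.start}"
            )

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class EventRecord:
    """One integration event: a vector fragment replacing a genomic interval.

    ``del_start > del_end`` (by exactly one) encodes a zero-length deletion,
    i.e. a clean insertion between ``del_end`` and ``del_start``.
    """

    chrom: str
    del_start: int
    del_end: int
    v_start: int
    v_end: int
    orientation: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.del_len < 0:
            raise ValueError(f"{self.label}: negative deletion length")
        if self.v_len < 1:
            raise ValueError(f"{self.label}: vector fragment length < 1")
        if self.orientation not in "+-":
            raise ValueError(f"{self.label}: orientation must be + or -")

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start + 1

    @property
    def v_len(self) -> int:
        return self.v_end - self.v_start + 1


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
            raise FormatError(
                f"{path}: record {rec.id!r} has non-ACGTN character "
                f"{seq[pos - 1]!r} at position {pos}"
            )
        records.append(SeqRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(bio)


# ---------------------------------------------------------------- FASTQ


def read_fastq(path: str | Path) -> list[FastqRecord]:
    out: list[FastqRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):  # Phred+33 ("fastq-sanger")
        quals = tuple(rec.letter_annotations["phred_quality"])
        out.append(FastqRecord(rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------- SAM

_CIGAR_NUM = {0: "M", 1: "I", 2: "D", 4: "S"}
_CIGAR_CODE = {v: k for k, v in _CIGAR_NUM.items()}


def read_sam(path: str | Path) -> list[AlnRecord]:
    """Read a text SAM file into AlnRecords.

    Only the 11 mandatory columns are interpreted; optional tags are ignored.
    Flag bits 0x1 (paired), 0x4 (unmapped), 0x10 (reverse), 0x100 (secondary)
    and 0x2 (proper pair) are mapped onto the named fields.
    """
    out: list[AlnRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            cigar: list[tuple[str, int]] = []
            if a.cigartuples:
                for code, n in a.cigartuples:
                    if code not in _CIGAR_NUM:
                        raise FormatError(
                            f"{a.query_name}: CIGAR op code {code} outside M/I/D/S dialect"
                        )
                    cigar.append((_CIGAR_NUM[code], n))
            rec = AlnRecord(
                query_id=a.query_name,
                ref_id=None if a.is_unmapped else a.reference_name,
                pos=0 if a.is_unmapped else a.reference_start + 1,
                strand="-" if a.is_reverse else "+",
                cigar=cigar,
                mapq=a.mapping_quality,
                is_paired=a.is_paired,
                mate_ref_id=a.next_reference_name if a.next_reference_id >= 0 else None,
                mate_pos=a.next_reference_start + 1 if a.next_reference_start >= 0 else None,
                unmapped=a.is_unmapped,
                secondary=a.is_secondary,
                proper_pair=a.is_proper_pair,
                seq=a.query_sequence,
            )
            out.append(rec.validate())
    return out


def write_sam(
    records: Iterable[AlnRecord],
    header_refs: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write AlnRecords as text SAM with @SQ lines from ``header_refs``."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in header_refs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        name_to_id = {name: i for i, (name, _) in enumerate(header_refs)}
        for r in records:
            r.validate()
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.query_id
            flag = 0
            if r.is_paired:
                flag |= 0x1
            if r.proper_pair:
                flag |= 0x2
            if r.unmapped:
                flag |= 0x4
            if r.strand == "-":
                flag |= 0x10
            if r.secondary:
                flag |= 0x100
            a.flag = flag
            if not r.unmapped:
                a.reference_id = name_to_id[r.ref_id]
                a.reference_start = r.pos - 1
                a.cigartuples = [(_CIGAR_CODE[op], n) for op, n in r.cigar]
            a.mapping_quality = r.mapq
            if r.mate_ref_id is not None:
                a.next_reference_id = name_to_id[r.mate_ref_id]
            if r.mate_pos is not None:
                a.next_reference_start = r.mate_pos - 1
            if r.seq is not None:
                a.query_sequence = r.seq
            fh.write(a)


# ---------------------------------------------------------------- GFF3


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if int(cols[4]) < int(cols[3]):
                raise FormatError(
                    f"{path}:{lineno}: end {cols[4]} < start {cols[3]}"
                )
            f = feature_from_line(line)
            attrs = {k: v[0] for k, v in f.attributes.items() if v}
            feats.append(
                GffFeature(f.seqid, f.featuretype, f.start, f.end, f.strand, attrs)
            )
    return feats


# ------------------------------------------------------- events (JSON/BED)


def write_events_json(events: Iterable[EventRecord], path: str | Path) -> None:
    payload = [
        {
            "chrom": e.chrom,
            "del_start": e.del_start,
            "del_end": e.del_end,
            "v_start": e.v_start,
            "v_end": e.v_end,
            "orientation": e.orientation,
            "label": e.label,
        }
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_events_json(path: str | Path) -> list[EventRecord]:
    payload = json.loads(Path(path).read_text())
    return [EventRecord(**item) for item in payload]


def write_events_bed(events: Iterable[EventRecord], path: str | Path) -> None:
    """BED6 of the genomic deletions (0-based half-open)."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                f"{e.chrom}\t{e.del_start - 1}\t{e.del_end}\t{e.label}\t0\t{e.orientation}\n"
            )


def read_events_bed(path: str | Path) -> list[EventRecord]:
    """Inverse of :func:`write_events_bed` for the deletion intervals.

    Vector coordinates are not representable in BED; they come back as the
    unit interval placeholder (1, 1) so the record stays constructible.
    """
    out: list[EventRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, label, _score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                EventRecord(
                    chrom=chrom,
                    del_start=int(s) + 1,
                    del_end=int(e),
                    v_start=1,
                    v_end=1,
                    orientation=strand,
                    label=label,
                )
            )
    return out
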