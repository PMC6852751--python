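"""Minimal k-mer-anchor read mapper for the composite reference.

The composite reference is the host genome plus the vector as one extra
contig. The mapper exists so the pipeline runs without external binaries; the
downstream screening accepts any SAM with the same dialect, so output from a
production mapper can be substituted.

Algorithm: exact k-mer seeding against a masked index, diagonal clustering of
anchors per (contig, strand), then edit-distance alignment (edlib) of the
read against the implied reference window. A read that crosses an insertion
junction fails whole-read alignment and is emitted as one primary alignment
with a terminal soft clip; the clipped fragment is re-mapped by the junction
screen, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .io_formats import AlnRecord, SeqRecord, revcomp

__all__ = [
    "KmerIndex",
    "MapParams",
    "build_index",
    "map_read",
    "map_paired",
    "align_banded",
]

_EDLIB_CIGAR = re.compile(r"(\d+)([=XIDS])")


@dataclass(frozen=True)
class MapParams:
    """Mapper tuning knobs.

    ``band`` is the acceptance threshold on whole-read edit distance,
    expressed as a fraction of read length; it also bounds the alignment
    search band. Defaults suit ~1% substitution short reads; use
    :meth:`long_read` for indel-rich long reads.
    """

    k: int = 15
    max_occ: int = 50
    band: float = 0.15
    min_chain_anchors: int = 2
    anchor_stride: int = 1
    insert_mean: int = 400
    insert_sd: int = 40

    def __post_init__(self) -> None:
        if not (9 <= self.k <= 31) or self.k % 2 == 0:
            raise ValueError("k must be odd and in [9, 31]")

    @classmethod
    def long_read(cls, **kw) -> "MapParams":
        kw.setdefault("k", 13)
        kw.setdefault("band", 0.25)
        kw.setdefault("anchor_stride", 3)
        return cls(**kw)


@dataclass
class KmerIndex:
    k: int
    max_occ: int
    table: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    n_masked: int = 0

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.table.get(kmer, [])


def build_index(refs: list[SeqRecord], params: MapParams) -> KmerIndex:
    """Index every ACGT-only k-mer; k-mers above the occurrence cap are
    dropped and counted."""
    k = params.k
    table: dict[str, list[tuple[str, int]]] = {}
    for ref in refs:
        seq = ref.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append((ref.id, i + 1))
    masked = [kmer for kmer, occ in table.items() if len(occ) > params.max_occ]
    for kmer in masked:
        del table[kmer]
    return KmerIndex(k=k, max_occ=params.max_occ, table=table, n_masked=len(masked))


def _collapse_cigar(ext_cigar: str) -> list[tuple[str, int]]:
    """Collapse edlib's extended CIGAR (=/X) into M/I/D runs."""
    out: list[tuple[str, int]] = []
    for num, op in _EDLIB_CIGAR.findall(ext_cigar):
        op = "M" if op in "=X" else op
        n = int(num)
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def align_banded(query: str, target: str, band: int) -> tuple[int, list[tuple[str, int]]]:
    """Global (NW) edit-distance alignment with unit costs.

    ``band`` caps the search; when the optimal distance exceeds it the
    alignment is recomputed unbounded, so the returned distance is always the
    full-DP optimum.
    """
    res = edlib.align(query, target, mode="NW", task="path", k=max(band, 0))
    if res["editDistance"] < 0:
        res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], _collapse_cigar(res["cigar"])


@dataclass
class _Cluster:
    ref_id: str
    strand: str
    anchors: list[tuple[int, int]]  # (query_pos, ref_pos), 1-based

    @property
    def score(self) -> int:
        return len(self.anchors)


def _collect_clusters(
    seq: str, strand: str, index: KmerIndex, params: MapParams, gap: int
) -> list[_Cluster]:
    k = index.k
    anchors_by_ref: dict[str, list[tuple[int, int]]] = {}
    for q in range(0, len(seq) - k + 1, params.anchor_stride):
        for ref_id, rpos in index.lookup(seq[q : q + k]):
            anchors_by_ref.setdefault(ref_id, []).append((rpos - q, q + 1, rpos))
    clusters: list[_Cluster] = []
    for ref_id, items in anchors_by_ref.items():
        items.sort()
        run: list[tuple[int, int, int]] = []
        for it in items:
            if run and it[0] - run[-1][0] > gap:
                clusters.append(_Cluster(ref_id, strand, [(q, r) for _, q, r in run]))
                run = []
            run.append(it)
        if run:
            clusters.append(_Cluster(ref_id, strand, [(q, r) for _, q, r in run]))
    for c in clusters:
        c.anchors.sort()
    return clusters


def _chain_span(c: _Cluster, k: int) -> tuple[int, int, int, int]:
    qs = c.anchors[0][0]
    qe = c.anchors[-1][0] + k - 1
    rs = min(r for _, r in c.anchors)
    re_ = max(r for _, r in c.anchors) + k - 1
    return qs, qe, rs, re_


def _extend_exact(seq: str, ref: str, qs: int, qe: int, rs: int, re_: int) -> tuple[int, int, int, int]:
    """Greedy exact extension of a matched span in both directions
    (1-based coordinates on both sequences)."""
    while qs > 1 and rs > 1 and seq[qs - 2] == ref[rs - 2]:
        qs -= 1
        rs -= 1
    while qe < len(seq) and re_ < len(ref) and seq[qe] == ref[re_]:
        qe += 1
        re_ += 1
    return qs, qe, rs, re_


def _mapq(best: int, second: int) -> int:
    return max(0, min(60, 6 * (best - second)))


def map_read(
    read_seq: str,
    index: KmerIndex,
    refs: list[SeqRecord],
    params: MapParams,
    read_id: str = "read",
) -> list[AlnRecord]:
    """Map one read; returns the primary alignment first (here: only), or a
    single record flagged unmapped when no chain is found."""
    if not read_seq:
        raise ValueError("empty read")
    read_seq = read_seq.upper()
    if len(read_seq) < index.k:
        return [_unmapped(read_id, read_seq)]
    ref_by_id = {r.id: r for r in refs}
    gap = max(50, int(params.band * len(read_seq)))
    clusters = _collect_clusters(read_seq, "+", index, params, gap)
    rc = revcomp(read_seq)
    clusters += _collect_clusters(rc, "-", index, params, gap)
    clusters = [c for c in clusters if c.score >= params.min_chain_anchors]
    if not clusters:
        return [_unmapped(read_id, read_seq)]
    # deterministic order: best score, then lexicographic ref, leftmost pos
    clusters.sort(key=lambda c: (-c.score, c.ref_id, c.anchors[0][1], c.strand))
    best = clusters[0]
    second_score = clusters[1].score if len(clusters) > 1 else 0
    tie = len(clusters) > 1 and clusters[1].score == best.score
    mapq = 0 if tie else _mapq(best.score, second_score)
    seq = read_seq if best.strand == "+" else rc
    ref = ref_by_id[best.ref_id].sequence
    rec = _align_cluster(seq, ref, best, index.k, params)
    if rec is None:
        return [_unmapped(read_id, read_seq)]
    pos, cigar = rec
    out = AlnRecord(
        query_id=read_id,
        ref_id=best.ref_id,
        pos=pos,
        strand=best.strand,
        cigar=cigar,
        mapq=mapq,
        seq=seq,
    )
    return [out.validate()]


def _unmapped(read_id: str, seq: str) -> AlnRecord:
    return AlnRecord(
        query_id=read_id,
        ref_id=None,
        pos=0,
        strand="+",
        cigar=[],
        mapq=0,
        unmapped=True,
        seq=seq,
    )


def _align_cluster(
    seq: str, ref: str, cluster: _Cluster, k: int, params: MapParams
) -> tuple[int, list[tuple[str, int]]] | None:
    """Align ``seq`` (already orientation-matched) around the cluster span.

    Tries whole-read infix alignment against the implied window first; when
    the distance exceeds the band (junction reads), aligns only the chained
    span and soft-clips the remainder.
    """
    L = len(seq)
    qs, qe, rs, re_ = _chain_span(cluster, k)  # all 1-based inclusive
    qs, qe, rs, re_ = _extend_exact(seq, ref, qs, qe, rs, re_)
    prefix = qs - 1  # unaligned read prefix length
    suffix = L - qe
    band = max(8, int(params.band * L))
    # whole-read window: chained ref span widened by the unaligned read tails
    w_start = max(0, (rs - 1) - prefix - band)
    w_end = min(len(ref), re_ + suffix + band)
    window = ref[w_start:w_end]
    res = edlib.align(seq, window, mode="HW", task="path", k=band)
    if res["editDistance"] >= 0:
        loc = res["locations"][0]
        return w_start + loc[0] + 1, _collapse_cigar(res["cigar"])
    # partial (junction) alignment: exact span plus terminal soft clips
    if qe - qs + 1 < k:
        return None
    sub = seq[qs - 1 : qe]
    target = ref[rs - 1 : re_]
    _, core = align_banded(sub, target, band)
    cigar: list[tuple[str, int]] = []
    if prefix > 0:
        cigar.append(("S", prefix))
    cigar.extend(core)
    if suffix > 0:
        cigar.append(("S", suffix))
    return rs, cigar


def map_paired(
    r1_seq: str,
    r2_seq: str,
    index: KmerIndex,
    refs: list[SeqRecord],
    params: MapParams,
    read_id: str = "pair",
) -> tuple[AlnRecord, AlnRecord]:
    """Map both mates and fill pairing flags.

    A pair is proper iff both mates map to the same contig on opposite
    strands with an implied insert within insert_mean +/- 4*insert_sd.
    """
    a1 = map_read(r1_seq, index, refs, params, read_id=read_id + "/1")[0]
    a2 = map_read(r2_seq, index, refs, params, read_id=read_id + "/2")[0]
    a1.is_paired = a2.is_paired = True
    proper = False
    if not a1.unmapped and not a2.unmapped:
        a1.mate_ref_id, a1.mate_pos = a2.ref_id, a2.pos
        a2.mate_ref_id, a2.mate_pos = a1.ref_id, a1.pos
        if a1.ref_id == a2.ref_id and a1.strand != a2.strand:
            left, right = sorted((a1, a2), key=lambda a: a.pos)
            insert = right.ref_end() - left.pos + 1
            lo = params.insert_mean - 4 * params.insert_sd
            hi = params.insert_mean + 4 * params.insert_sd
            proper = lo <= insert <= hi
    a1.proper_pair = a2.proper_pair = proper
    return a1, a2
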