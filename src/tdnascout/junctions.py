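"""Core inference: from chimeric read evidence to resolved integration calls.

The chain mirrors the screening logic of T-DNA localization by whole-genome
re-sequencing: read pairs with one mate on the vector contig and split reads
whose clipped tail maps to the vector flag suspicious sites; sites are
clustered windows of such evidence; long reads overlapping a site are
extracted, polished with the accurate short reads, and kept only if they
actually contain vector sequence; the surviving reads are decomposed into
(left genome flank | vector fragment | right genome flank) to give the
deletion interval, the inserted vector interval and its orientation.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
import numpy as np

from .io_formats import AlnRecord, FastqRecord, SeqRecord, revcomp
from .litemap import KmerIndex, MapParams, map_read

__all__ = [
    "DiscordantPair",
    "SplitRead",
    "CandidateSite",
    "CorrectedLongRead",
    "EventCall",
    "screen_discordant",
    "screen_splits",
    "cluster_candidates",
    "extract_target_longreads",
    "correct_longread",
    "correct_longreads",
    "tdna_containment",
    "resolve_breakpoints",
    "qc_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_CLIP = 15
DEFAULT_MIN_EVIDENCE = 3
DEFAULT_FLANK = 2000
DEFAULT_RESOLVE_FLANK = 5000


@dataclass(frozen=True)
class DiscordantPair:
    """A read pair with exactly one mate on the vector contig."""

    pair_id: str
    genome_mate: tuple[str, int, str]  # (ref_id, pos, strand)
    vector_mate: tuple[int, str]  # (pos, strand)


@dataclass(frozen=True)
class SplitRead:
    """A genome-aligned read with a soft-clipped tail, re-mapped elsewhere.

    ``junction_pos`` is the last (clip_side 'right') or first (clip_side
    'left') aligned genome base, i.e. the host base adjacent to the clip.
    ``clip_pos`` is the coordinate, on the clip's target, of the clip base
    adjacent to the junction (None when unplaced).
    """

    read_id: str
    ref_id: str
    junction_pos: int
    clip_side: str  # 'left' | 'right'
    clip_seq: str
    clip_target: str  # 'vector' | 'genome' | 'unplaced'
    clip_pos: int | None


@dataclass
class CandidateSite:
    """A clustered window of junction evidence on one contig."""

    chrom: str
    window_start: int
    window_end: int
    pairs: list[DiscordantPair] = field(default_factory=list)
    splits: list[SplitRead] = field(default_factory=list)

    @property
    def pair_support(self) -> int:
        return len(self.pairs)

    @property
    def split_support(self) -> int:
        return len(self.splits)


@dataclass
class CorrectedLongRead:
    read_id: str
    sequence: str
    corrected_fraction: float
    contains_tdna: bool = False


@dataclass
class EventCall:
    """A resolved (or partially resolved) integration event."""

    chrom: str
    del_start: int
    del_end: int
    v_start: int | None
    v_end: int | None
    orientation: str | None
    label: str = ""
    support: dict[str, int] = field(default_factory=dict)
    status: str = "candidate"  # candidate | confirmed | excluded
    breakpoint_ci: int = 0
    # which junctions long reads actually spanned; a large deletion shows up
    # as two one-sided sites ("left",) and ("right",) that the pipeline merges
    junctions_observed: tuple[str, ...] = ()

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start + 1

    @property
    def v_len(self) -> int | None:
        if self.v_start is None or self.v_end is None:
            return None
        return self.v_end - self.v_start + 1


# ------------------------------------------------------------ screening


def screen_discordant(
    aln_pairs: list[tuple[AlnRecord, AlnRecord]],
    vector_name: str,
    ref_names: list[str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[DiscordantPair]:
    """Keep pairs with one primary mate on the vector and one on a genome
    contig, both mapped at or above ``min_mapq``."""
    if vector_name not in ref_names:
        raise ValueError(f"vector contig {vector_name!r} absent from reference")
    out: list[DiscordantPair] = []
    for a, b in aln_pairs:
        if a.unmapped or b.unmapped or a.secondary or b.secondary:
            continue
        if a.mapq < min_mapq or b.mapq < min_mapq:
            continue
        on_vec = [r.ref_id == vector_name for r in (a, b)]
        if sum(on_vec) != 1:
            continue
        vec, gen = (a, b) if on_vec[0] else (b, a)
        pair_id = a.query_id.rsplit("/", 1)[0]
        out.append(
            DiscordantPair(
                pair_id=pair_id,
                genome_mate=(gen.ref_id, gen.pos, gen.strand),
                vector_mate=(vec.pos, vec.strand),
            )
        )
    return out


def screen_splits(
    alns: list[AlnRecord],
    refs: list[SeqRecord],
    index: KmerIndex,
    vector_name: str,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    clip_params: MapParams | None = None,
) -> list[SplitRead]:
    """Turn terminal soft clips on genome alignments into split-read evidence
    by re-mapping the clipped fragment against the composite reference."""
    if clip_params is None:
        clip_params = MapParams(k=13, min_chain_anchors=1, max_occ=index.max_occ)
    clip_index = index
    if clip_index.k != clip_params.k:
        from .litemap import build_index

        clip_index = build_index(refs, clip_params)
    out: list[SplitRead] = []
    for a in alns:
        if a.unmapped or a.secondary or a.ref_id == vector_name:
            continue
        if a.mapq < min_mapq or not a.cigar or a.seq is None:
            continue
        sides = []
        if a.cigar[0][0] == "S" and a.cigar[0][1] >= min_clip:
            sides.append(("left", a.seq[: a.cigar[0][1]], a.pos))
        if a.cigar[-1][0] == "S" and a.cigar[-1][1] >= min_clip:
            sides.append(("right", a.seq[-a.cigar[-1][1] :], a.ref_end()))
        for side, clip_seq, junction_pos in sides:
            hit = map_read(clip_seq, clip_index, refs, clip_params)[0]
            if hit.unmapped:
                target, clip_pos = "unplaced", None
            else:
                target = "vector" if hit.ref_id == vector_name else "genome"
                # coordinate of the clip base that touches the junction
                if side == "right":
                    clip_pos = hit.pos if hit.strand == "+" else hit.ref_end()
                else:
                    clip_pos = hit.ref_end() if hit.strand == "+" else hit.pos
            out.append(
                SplitRead(
                    read_id=a.query_id,
                    ref_id=a.ref_id,
                    junction_pos=junction_pos,
                    clip_side=side,
                    clip_seq=clip_seq,
                    clip_target=target,
                    clip_pos=clip_pos,
                )
            )
    return out


# ------------------------------------------------------------ clustering


def cluster_candidates(
    pairs: list[DiscordantPair],
    splits: list[SplitRead],
    window: int = 560,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
) -> list[CandidateSite]:
    """Single-linkage clustering of genome-side evidence positions with gap
    <= window; only splits whose clip maps to the vector count as evidence."""
    items: dict[str, list[tuple[int, object]]] = {}
    for p in pairs:
        chrom, pos, _ = p.genome_mate
        items.setdefault(chrom, []).append((pos, p))
    for s in splits:
        if s.clip_target != "vector":
            continue
        items.setdefault(s.ref_id, []).append((s.junction_pos, s))
    sites: list[CandidateSite] = []
    for chrom in sorted(items):
        evidence = sorted(items[chrom], key=lambda t: t[0])
        run: list[tuple[int, object]] = []
        for ev in evidence:
            if run and ev[0] - run[-1][0] > window:
                sites.append(_make_site(chrom, run))
                run = []
            run.append(ev)
        if run:
            sites.append(_make_site(chrom, run))
    sites = [
        s for s in sites if s.pair_support + s.split_support >= min_evidence
    ]
    sites.sort(key=lambda s: (s.chrom, s.window_start))
    return sites


def _make_site(chrom: str, run: list[tuple[int, object]]) -> CandidateSite:
    site = CandidateSite(
        chrom=chrom, window_start=run[0][0], window_end=run[-1][0]
    )
    for _, ev in run:
        if isinstance(ev, DiscordantPair):
            site.pairs.append(ev)
        else:
            site.splits.append(ev)
    return site


def extract_target_longreads(
    long_alns: list[AlnRecord],
    sites: list[CandidateSite],
    flank: int = DEFAULT_FLANK,
) -> set[str]:
    """Ids of long reads whose primary genome alignment intersects any site
    window widened by ``flank``."""
    out: set[str] = set()
    for a in long_alns:
        if a.unmapped or a.secondary:
            continue
        for s in sites:
            if a.ref_id != s.chrom:
                continue
            if a.pos <= s.window_end + flank and a.ref_end() >= s.window_start - flank:
                out.add(a.query_id)
                break
    return out


# ------------------------------------------------------------ correction

_VOTE_DEL = 4
_VOTE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte codes


class _Pileup:
    """Vote accumulator over the columns of one long read."""

    def __init__(self, seq: str):
        self.seq = seq
        self.votes = np.zeros((5, len(seq)), dtype=np.int32)
        self.insertions: dict[int, Counter] = {}

    def add(self, short_seq: str, window_start: int, window: str, band: int) -> None:
        res = edlib.align(short_seq, window, mode="HW", task="path", k=band)
        if res["editDistance"] < 0:
            return
        loc = res["locations"][0]
        # an alignment flush against the window edge is usually a short read
        # that truly overhangs the long read (or the window) with its
        # overhang crammed in as spurious edits; its votes are poison at the
        # low-coverage edge columns, so drop it
        if loc[0] == 0 or loc[1] >= len(window) - 1:
            return
        w0 = loc[0]  # window-local start of the alignment
        # indel placement in repeats is ambiguous and edlib's choice depends
        # on the window cut, so votes from different short reads would land
        # on different columns; left-normalizing every indel run makes the
        # votes coherent.
        base_votes: list[tuple[int, int]] = []  # (absolute col, base idx)
        del_cols: list[int] = []
        ins_events: list[tuple[int, str]] = []  # (attach col, inserted seq)
        col = window_start + w0  # absolute column on the long read
        wcol = w0  # same position, window-local (for content checks)
        q = 0
        for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
            n = int(num)
            if op in "=X":
                for j in range(n):
                    b = _VOTE_IDX.get(ord(short_seq[q + j]))
                    if b is not None:
                        base_votes.append((col + j, b))
                col += n
                wcol += n
                q += n
            elif op == "D":  # long-read bases absent from the short read
                s = 0
                while (
                    s < len(base_votes)
                    and wcol - s - 1 >= 0
                    and base_votes[-(s + 1)][0] == col - s - 1
                    and window[wcol - s - 1] == window[wcol - s - 1 + n]
                ):
                    s += 1
                if s:  # shift the deletion left across the repeat
                    moved = base_votes[-s:]
                    del base_votes[-s:]
                    base_votes.extend((c + n, b) for c, b in moved)
                del_cols.extend(range(col - s, col - s + n))
                col += n
                wcol += n
            else:  # 'I': extra short-read bases => insertion after a column
                s = 0
                while (
                    s < len(base_votes)
                    and q - s - 1 >= 0
                    and base_votes[-(s + 1)][0] == col - s - 1
                    and short_seq[q - s - 1] == short_seq[q - s - 1 + n]
                ):
                    s += 1
                attach = col - 1 - s
                if attach >= 0:
                    ins_events.append((attach, short_seq[q - s : q - s + n]))
                q += n
        for c, b in base_votes:
            self.votes[b, c] += 1
        for c in del_cols:
            self.votes[_VOTE_DEL, c] += 1
        for c, ins in ins_events:
            self.insertions.setdefault(c, Counter())[ins] += 1

    def consensus(self, min_cov: int) -> tuple[str, float]:
        seq = self.seq
        n = len(seq)
        cov = self.votes.sum(axis=0)
        out: list[str] = []
        bases = "ACGT"
        for c in range(n):
            emitted = seq[c]
            if cov[c] >= min_cov:
                col = self.votes[:, c]
                best = int(col.max())
                orig_idx = _VOTE_IDX.get(ord(seq[c]), None)
                # tie-break: keep the original base when it is among the best
                if orig_idx is not None and col[orig_idx] == best:
                    winner = orig_idx
                else:
                    winner = int(col.argmax())
                emitted = "" if winner == _VOTE_DEL else bases[winner]
            out.append(emitted)
            ins_counter = self.insertions.get(c)
            if ins_counter and cov[c] >= min_cov:
                ins, count = ins_counter.most_common(1)[0]
                if count >= min_cov and count > cov[c] / 2:
                    out.append(ins)
        frac = float((cov >= min_cov).sum()) / n if n else 0.0
        return "".join(out), frac


def correct_longreads(
    long_reads: list[FastqRecord],
    short_reads: list[FastqRecord],
    k: int = 13,
    min_cov: int = 3,
    max_kmer_occ: int = 16,
) -> list[CorrectedLongRead]:
    """Polish long reads by pileup majority vote of short reads.

    Short reads are anchored to long reads through shared exact k-mers, then
    aligned with edit distance; per column the majority over covering
    short-read bases (including deletion votes) replaces the long-read base
    when coverage >= min_cov; a majority insertion is spliced in. Columns
    below min_cov coverage are left untouched.
    """
    if not short_reads:
        return [CorrectedLongRead(r.id, r.sequence, 0.0) for r in long_reads]
    table: dict[str, list[tuple[int, int]]] = {}
    for i, lr in enumerate(long_reads):
        seq = lr.sequence
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            occ = table.setdefault(kmer, [])
            if len(occ) < max_kmer_occ:
                occ.append((i, p))
    pileups = [_Pileup(lr.sequence) for lr in long_reads]
    for sr in short_reads:
        for seq in (sr.sequence, revcomp(sr.sequence)):
            hits: dict[int, int] = {}
            for q in range(0, len(seq) - k + 1, k):
                for i, p in table.get(seq[q : q + k], ()):
                    hits.setdefault(i, p - q)
            for i, start in hits.items():
                lr_seq = long_reads[i].sequence
                pad = 10 + len(seq) // 5
                w_start = max(0, start - pad)
                w_end = min(len(lr_seq), start + len(seq) + pad)
                pileups[i].add(
                    seq, w_start, lr_seq[w_start:w_end], band=len(seq) // 3
                )
    out = []
    for lr, pile in zip(long_reads, pileups):
        seq, frac = pile.consensus(min_cov)
        out.append(CorrectedLongRead(lr.id, seq, frac))
    return out


def correct_longread(
    long_read: FastqRecord,
    short_reads: list[FastqRecord],
    k: int = 13,
    min_cov: int = 3,
) -> CorrectedLongRead:
    """Single-read convenience wrapper around :func:`correct_longreads`."""
    return correct_longreads([long_read], short_reads, k=k, min_cov=min_cov)[0]


# ------------------------------------------------------------ containment


@lru_cache(maxsize=4)
def _vector_kmers(vector_seq: str, k: int) -> frozenset[str]:
    both = vector_seq + "#" + revcomp(vector_seq)
    kmers = set()
    for half in both.split("#"):
        for i in range(len(half) - k + 1):
            kmers.add(half[i : i + k])
    return frozenset(kmers)


def tdna_containment(
    read_seq: str, vector_seq: str, k: int = 21, min_hits: int = 5
) -> bool:
    """True iff the read shares >= min_hits distinct exact k-mers with the
    vector or its reverse complement."""
    kmers = _vector_kmers(vector_seq, k)
    seen: set[str] = set()
    for i in range(len(read_seq) - k + 1):
        kmer = read_seq[i : i + k]
        if kmer in kmers:
            seen.add(kmer)
            if len(seen) >= min_hits:
                return True
    return False


# ------------------------------------------------------------ resolution


def _anchor_map(seq: str, target: str, k: int, max_occ: int = 4) -> list[tuple[int, int]]:
    """(query_pos, target_pos) 1-based anchor pairs via exact k-mers unique
    enough in the target."""
    table: dict[str, list[int]] = {}
    for p in range(len(target) - k + 1):
        kmer = target[p : p + k]
        occ = table.setdefault(kmer, [])
        if len(occ) <= max_occ:
            occ.append(p + 1)
    out = []
    for q in range(len(seq) - k + 1):
        occ = table.get(seq[q : q + k])
        if occ and len(occ) <= 1:
            out.append((q + 1, occ[0]))
    return out


def _offset_clusters(
    anchors: list[tuple[int, int]],
    max_offset_jump: int = 15,
    max_query_gap: int = 200,
    min_anchors: int = 3,
) -> list[list[tuple[int, int]]]:
    """Split q-sorted anchors into runs of consistent diagonal; a jump in
    offset or a long anchor-free query stretch starts a new segment."""
    anchors = sorted(anchors)
    runs: list[list[tuple[int, int]]] = []
    run: list[tuple[int, int]] = []
    for q, t in anchors:
        if run:
            pq, pt = run[-1]
            if abs((t - q) - (pt - pq)) > max_offset_jump or q - pq > max_query_gap:
                runs.append(run)
                run = []
        run.append((q, t))
    if run:
        runs.append(run)
    return [r for r in runs if len(r) >= min_anchors]


def _extend_right(a: str, ia: int, b: str, ib: int) -> tuple[int, int]:
    """Extend exact match rightward from 1-based positions; returns the last
    matching positions."""
    while ia < len(a) and ib < len(b) and a[ia] == b[ib]:
        ia += 1
        ib += 1
    return ia, ib


def _extend_left(a: str, ia: int, b: str, ib: int) -> tuple[int, int]:
    while ia > 1 and ib > 1 and a[ia - 2] == b[ib - 2]:
        ia -= 1
        ib -= 1
    return ia, ib


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def resolve_breakpoints(
    site: CandidateSite,
    confirmed_reads: list[CorrectedLongRead],
    genome: dict[str, str],
    vector: str,
    k: int = 21,
    flank: int = DEFAULT_RESOLVE_FLANK,
) -> EventCall:
    """Resolve a site into an event call by three-segment decomposition of
    the vector-containing long reads.

    Each read is oriented to the genome forward strand, decomposed into
    genome- and vector-anchored diagonal segments, and each junction it spans
    contributes per-read estimates of del_start/del_end (genome side) and
    v_start/v_end (vector side, by orientation). Estimates are aggregated by
    the lower median; the CI is the maximum absolute deviation from it.
    Reads decomposing into four or more segments are excluded as complex.
    """
    chrom_seq = genome[site.chrom]
    gs = max(1, site.window_start - flank)
    ge = min(len(chrom_seq), site.window_end + flank)
    gwin = chrom_seq[gs - 1 : ge]
    usable = [r for r in confirmed_reads if r.contains_tdna]
    support_reads = 0
    del_starts: list[int] = []
    del_ends: list[int] = []
    v_starts: list[int] = []
    v_ends: list[int] = []
    orientations: list[str] = []
    rcv = revcomp(vector)
    L = len(vector)
    for read in usable:
        best = None
        for seq in (read.sequence, revcomp(read.sequence)):
            g_anchors = _anchor_map(seq, gwin, k)
            if best is None or len(g_anchors) > len(best[1]):
                best = (seq, g_anchors)
        seq, g_anchors = best
        g_runs = _offset_clusters(g_anchors)
        v_runs_f = _offset_clusters(_anchor_map(seq, vector, k))
        v_runs_r = _offset_clusters(_anchor_map(seq, rcv, k))
        v_all = [("+", r) for r in v_runs_f] + [("-", r) for r in v_runs_r]
        if not g_runs or not v_all:
            continue
        if len(g_runs) + len(v_all) > 3:
            logger.warning(
                "read %s decomposes into %d segments; excluded as complex",
                read.read_id,
                len(g_runs) + len(v_all),
            )
            continue
        strand, v_run = max(v_all, key=lambda t: len(t[1]))
        v_mid = (v_run[0][0] + v_run[-1][0] + k - 1) / 2
        contributed = False
        for g_run in g_runs:
            g_mid = (g_run[0][0] + g_run[-1][0] + k - 1) / 2
            if g_mid < v_mid:  # left genome flank | vector
                q, t = g_run[-1]
                q_end, t_end = _extend_right(seq, q + k - 1, gwin, t + k - 1)
                del_starts.append(gs + t_end)  # first deleted base
                q, t = v_run[0]
                q0, t0 = _extend_left(seq, q, _target_of(strand, vector, rcv), t)
                if strand == "+":
                    v_starts.append(t0)
                else:
                    v_ends.append(L - t0 + 1)
                contributed = True
            else:  # vector | right genome flank
                q, t = g_run[0]
                q0, t0 = _extend_left(seq, q, gwin, t)
                del_ends.append(gs + t0 - 2)  # last deleted base
                q, t = v_run[-1]
                q_end, t_end = _extend_right(
                    seq, q + k - 1, _target_of(strand, vector, rcv), t + k - 1
                )
                if strand == "+":
                    v_ends.append(t_end)
                else:
                    v_starts.append(L - t_end + 1)
                contributed = True
        if contributed:
            orientations.append(strand)
            support_reads += 1

    support = {
        "pairs": site.pair_support,
        "splits": site.split_support,
        "long_reads": support_reads,
    }
    if not (del_starts or del_ends):
        # only pair/split evidence: report the window, no vector interval
        return EventCall(
            chrom=site.chrom,
            del_start=site.window_start,
            del_end=site.window_end,
            v_start=None,
            v_end=None,
            orientation=None,
            support=support,
            status="candidate",
            breakpoint_ci=site.window_end - site.window_start,
        )
    calls = {
        "del_start": del_starts,
        "del_end": del_ends,
        "v_start": v_starts,
        "v_end": v_ends,
    }
    med = {name: _lower_median(v) for name, v in calls.items() if v}
    ci = max(
        (abs(x - med[name]) for name, v in calls.items() if v for x in v),
        default=0,
    )
    orientation = Counter(orientations).most_common(1)[0][0] if orientations else None
    observed = tuple(
        side for side, seen in (("left", del_starts), ("right", del_ends)) if seen
    )
    return EventCall(
        chrom=site.chrom,
        del_start=med.get("del_start", site.window_start),
        del_end=med.get("del_end", site.window_end),
        v_start=med.get("v_start"),
        v_end=med.get("v_end"),
        orientation=orientation,
        support=support,
        status="confirmed",
        breakpoint_ci=ci,
        junctions_observed=observed,
    )


def _target_of(strand: str, vector: str, rcv: str) -> str:
    return vector if strand == "+" else rcv


def merge_one_sided_calls(calls: list["EventCall"]) -> list["EventCall"]:
    """Merge complementary one-sided calls into single events.

    When the deleted interval is much larger than the clustering window, the
    two junctions of one integration surface as two separate sites: the left
    one resolves only del_start (plus one vector bound), the right one only
    del_end (plus the other bound). Adjacent confirmed one-sided calls on the
    same contig with consistent orientation and a well-formed combined vector
    interval are folded into one call; everything else passes through.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.del_start, c.del_end))
    out: list[EventCall] = []
    i = 0
    while i < len(calls):
        c = calls[i]
        if i + 1 < len(calls):
            d = calls[i + 1]
            mergeable = (
                c.status == "confirmed"
                and d.status == "confirmed"
                and c.junctions_observed == ("left",)
                and d.junctions_observed == ("right",)
                and c.chrom == d.chrom
                and c.orientation == d.orientation
                and d.del_end >= c.del_start
            )
            if mergeable:
                v_start = c.v_start if c.v_start is not None else d.v_start
                v_end = c.v_end if c.v_end is not None else d.v_end
                if v_start is not None and v_end is not None and v_start <= v_end:
                    keys = set(c.support) | set(d.support)
                    out.append(
                        EventCall(
                            chrom=c.chrom,
                            del_start=c.del_start,
                            del_end=d.del_end,
                            v_start=v_start,
                            v_end=v_end,
                            orientation=c.orientation,
                            label=c.label or d.label,
                            support={
                                k: c.support.get(k, 0) + d.support.get(k, 0)
                                for k in sorted(keys)
                            },
                            status="confirmed",
                            breakpoint_ci=max(c.breakpoint_ci, d.breakpoint_ci),
                            junctions_observed=("left", "right"),
                        )
                    )
                    i += 2
                    continue
        out.append(c)
        i += 1
    return out


# ------------------------------------------------------------ QC


def qc_summary(
    alns: list[AlnRecord],
    fastqs: list[FastqRecord],
    refs: list[SeqRecord],
) -> dict[str, float]:
    """Mapping and base-quality summary of one read set."""
    primaries = [a for a in alns if not a.secondary]
    mapped = [a for a in primaries if not a.unmapped]
    total_reads = len(fastqs) if fastqs else len(primaries)
    aligned_bases = sum(n for a in mapped for op, n in a.cigar if op == "M")
    ref_len = sum(len(r) for r in refs)
    total_bases = sum(len(r.sequence) for r in fastqs)
    q30 = sum(1 for r in fastqs for q in r.qualities if q >= 30)
    return {
        "mapped_fraction": len(mapped) / total_reads if total_reads else 0.0,
        "mean_depth": aligned_bases / ref_len if ref_len else 0.0,
        "q30_fraction": q30 / total_bases if total_bases else 0.0,
        "mean_read_len": total_bases / total_reads if total_reads else 0.0,
    }
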