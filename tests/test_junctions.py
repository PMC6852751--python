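"""Junction screening, clustering, hybrid correction, containment filtering
and breakpoint resolution."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnascout import litemap, simgen
from tdnascout.io_formats import AlnRecord, FastqRecord, SeqRecord, revcomp
from tdnascout.junctions import (
    CandidateSite,
    DiscordantPair,
    EventCall,
    SplitRead,
    cluster_candidates,
    correct_longread,
    correct_longreads,
    extract_target_longreads,
    merge_one_sided_calls,
    qc_summary,
    resolve_breakpoints,
    screen_discordant,
    screen_splits,
    tdna_containment,
)

VEC = "TDNA_vector"


def _aln(ref="c1", pos=100, mapq=30, strand="+", cigar=None, qid="r/1", **kw):
    cigar = cigar or [("M", 100)]
    seq = kw.pop("seq", "A" * sum(n for op, n in cigar if op in "MIS"))
    return AlnRecord(
        query_id=qid, ref_id=ref, pos=pos, strand=strand, cigar=cigar,
        mapq=mapq, seq=seq, **kw,
    )


# ------------------------------------------------------------ discordant


def test_discordant_requires_exactly_one_vector_mate():
    pairs = [
        (_aln(ref="c1"), _aln(ref="c2", qid="r/2")),  # both genome
        (_aln(ref="c1"), _aln(ref=VEC, qid="r2/2")),  # genome + vector
        (_aln(ref=VEC), _aln(ref=VEC, qid="r3/2")),  # both vector
    ]
    out = screen_discordant(pairs, VEC, ["c1", "c2", VEC])
    assert len(out) == 1
    assert out[0].genome_mate[0] == "c1"


def test_discordant_enforces_mapq_threshold():
    pair = (_aln(ref="c1", mapq=10), _aln(ref=VEC, qid="x/2"))
    assert screen_discordant([pair], VEC, ["c1", VEC], min_mapq=20) == []
    assert len(screen_discordant([pair], VEC, ["c1", VEC], min_mapq=10)) == 1


def test_discordant_missing_vector_contig_is_error():
    with pytest.raises(ValueError, match="vector"):
        screen_discordant([], VEC, ["c1", "c2"])


def test_discordant_pairs_cluster_near_true_breakpoints(small_fixture):
    """Error-free pairs: every discordant genome mate lies within one insert
    span of a true junction."""
    fx = small_fixture
    composite = fx.genome + [fx.vector]
    params = litemap.MapParams()
    idx = litemap.build_index(composite, params)
    r1, r2 = simgen.simulate_short_reads(
        fx.mutant, simgen.ShortReadParams(depth=10, sub_rate=0.0, seed=13)
    )
    pairs = []
    for a, b in zip(r1, r2):
        pairs.append(litemap.map_paired(a.sequence, b.sequence, idx, composite, params,
                                        read_id=a.id[:-2]))
    disc = screen_discordant(pairs, VEC, [c.id for c in composite])
    assert disc
    max_dist = 400 + 4 * 40
    junctions_by_chrom = {
        "contig1": [fx.events[0].del_start, fx.events[0].del_end],
        "contig2": [fx.events[1].del_start, fx.events[1].del_end],
    }
    for p in disc:
        chrom, pos, _ = p.genome_mate
        assert min(abs(pos - j) for j in junctions_by_chrom[chrom]) <= max_dist


# ------------------------------------------------------------ splits


def test_fully_matched_read_yields_no_split(small_fixture):
    fx = small_fixture
    composite = fx.genome + [fx.vector]
    idx = litemap.build_index(composite, litemap.MapParams(k=13, min_chain_anchors=1))
    out = screen_splits([_aln(ref="contig1")], composite, idx, VEC)
    assert out == []


def test_right_clip_junction_position_arithmetic(small_fixture):
    fx = small_fixture
    composite = fx.genome + [fx.vector]
    idx = litemap.build_index(composite, litemap.MapParams(k=13, min_chain_anchors=1))
    rec = _aln(ref="contig1", pos=500, cigar=[("M", 60), ("S", 40)],
               seq=fx.genome[0].sequence[499:559] + "T" * 40)
    (sr,) = screen_splits([rec], composite, idx, VEC)
    assert sr.junction_pos == 500 + 59
    assert sr.clip_side == "right"
    assert sr.clip_target == "unplaced"  # poly-T clip maps nowhere


def test_junction_read_clip_maps_to_true_vector_breakpoint(small_fixture):
    """An error-free read crossing the forward event's left junction has its
    clip placed at the vector fragment start."""
    fx = small_fixture
    e = fx.events[0]
    composite = fx.genome + [fx.vector]
    params = litemap.MapParams()
    idx = litemap.build_index(composite, params)
    read = (
        fx.genome[0].sequence[e.del_start - 61 : e.del_start - 1]
        + fx.vector.sequence[e.v_start - 1 : e.v_start + 39]
    )
    (aln,) = litemap.map_read(read, idx, composite, params, read_id="j")
    clip_idx = litemap.build_index(composite, litemap.MapParams(k=13, min_chain_anchors=1))
    (sr,) = screen_splits([aln], composite, clip_idx, VEC)
    assert sr.clip_target == "vector"
    assert sr.junction_pos == e.del_start - 1
    assert sr.clip_pos == e.v_start


# ------------------------------------------------------------ clustering


def test_no_evidence_gives_no_sites():
    assert cluster_candidates([], [], window=560) == []


def test_separated_evidence_groups_make_two_sites():
    pairs = [
        DiscordantPair(f"p{i}", ("c1", 1000 + i * 10, "+"), (50, "+")) for i in range(3)
    ] + [
        DiscordantPair(f"q{i}", ("c1", 11_000 + i * 10, "+"), (50, "+")) for i in range(3)
    ]
    sites = cluster_candidates(pairs, [], window=560)
    assert len(sites) == 2
    assert sites[0].window_start == 1000 and sites[1].window_start == 11_000


def test_min_evidence_threshold_applies():
    pairs = [DiscordantPair("p", ("c1", 1000, "+"), (50, "+"))]
    assert cluster_candidates(pairs, [], window=560, min_evidence=2) == []
    assert len(cluster_candidates(pairs, [], window=560, min_evidence=1)) == 1


@given(
    positions=st.lists(st.integers(1, 200_000), min_size=0, max_size=40),
    thresholds=st.tuples(st.integers(1, 6), st.integers(1, 6)),
)
@settings(max_examples=40, deadline=None)
def test_raising_min_evidence_never_adds_sites(positions, thresholds):
    lo, hi = min(thresholds), max(thresholds)
    pairs = [
        DiscordantPair(f"p{i}", ("c1", pos, "+"), (1, "+"))
        for i, pos in enumerate(positions)
    ]
    n_lo = len(cluster_candidates(pairs, [], window=560, min_evidence=lo))
    n_hi = len(cluster_candidates(pairs, [], window=560, min_evidence=hi))
    assert n_hi <= n_lo


def test_non_vector_clips_are_not_clustering_evidence():
    splits = [
        SplitRead(f"s{i}", "c1", 5000 + i, "right", "A" * 20, "genome", 77)
        for i in range(5)
    ]
    assert cluster_candidates([], splits, window=560) == []


# ------------------------------------------------------------ extraction


def test_extraction_boundary_conditions():
    site = CandidateSite("c1", 10_000, 10_500)
    far = _aln(ref="c1", pos=200_000, qid="far", cigar=[("M", 5000)], seq=None)
    touching = _aln(ref="c1", pos=7999, qid="touch", cigar=[("M", 2)], seq=None)
    outside = _aln(ref="c1", pos=7997, qid="out", cigar=[("M", 2)], seq=None)
    ids = extract_target_longreads([far, touching, outside], [site], flank=2000)
    assert ids == {"touch"}


def test_every_junction_spanning_long_read_is_extracted(small_fixture):
    fx = small_fixture
    composite = fx.genome + [fx.vector]
    params = litemap.MapParams.long_read()
    idx = litemap.build_index(composite, params)
    reads = simgen.simulate_long_reads(
        fx.mutant, simgen.LongReadParams(depth=5, sub_rate=0, ins_rate=0, del_rate=0, seed=15)
    )
    alns = [litemap.map_read(r.sequence, idx, composite, params, read_id=r.id)[0]
            for r in reads]
    e = fx.events[0]
    sites = [CandidateSite("contig1", e.del_start - 100, e.del_start + 100)]
    ids = extract_target_longreads(alns, sites, flank=2000)
    # truth: reads whose mutant-haplotype span crosses the left junction
    for r in reads:
        _, contig, start, _ = r.id.split("/")
        if contig != "contig1":
            continue
        start = int(start)
        if start < e.del_start - 3000 and start + len(r.sequence) > e.del_start + 3000:
            assert r.id in ids


# ------------------------------------------------------------ correction


def test_correction_is_fixed_point_on_error_free_read(small_fixture):
    fx = small_fixture
    r1, r2 = simgen.simulate_short_reads(
        fx.mutant, simgen.ShortReadParams(depth=25, sub_rate=0.0, seed=16)
    )
    lr = FastqRecord("lr/contig1/5000/+", fx.mutant[0].sequence[4999:8999], (12,) * 4000)
    out = correct_longread(lr, r1 + r2)
    assert out.sequence == lr.sequence
    assert out.corrected_fraction > 0.9


def test_correction_without_short_reads_returns_unchanged():
    lr = FastqRecord("lr", "ACGT" * 100, (12,) * 400)
    out = correct_longread(lr, [])
    assert out.sequence == lr.sequence
    assert out.corrected_fraction == 0.0


def test_correction_fixes_most_substitution_errors(small_fixture):
    fx = small_fixture
    rng = random.Random(99)
    truth = fx.mutant[0].sequence[3000:7000]
    noisy = list(truth)
    err_pos = [i for i in range(len(noisy)) if rng.random() < 0.05]
    for i in err_pos:
        noisy[i] = rng.choice([b for b in "ACGT" if b != noisy[i]])
    r1, r2 = simgen.simulate_short_reads(
        fx.mutant, simgen.ShortReadParams(depth=30, sub_rate=0.0, seed=17)
    )
    out = correct_longread(FastqRecord("lr", "".join(noisy), (12,) * len(noisy)), r1 + r2)
    assert len(out.sequence) == len(truth)
    fixed = sum(1 for i in err_pos if out.sequence[i] == truth[i])
    assert fixed / len(err_pos) >= 0.95


def test_correction_below_coverage_changes_nothing():
    lr = FastqRecord("lr", "ACGTACGTACGTACGTACGTACGTACGT", (12,) * 28)
    # a single matching short read cannot reach min_cov=3
    srs = [FastqRecord("s/1", lr.sequence[2:22], (30,) * 20)]
    out = correct_longread(lr, srs, min_cov=3)
    assert out.sequence == lr.sequence
    assert out.corrected_fraction == 0.0


# ------------------------------------------------------------ containment


def test_containment_rejects_pure_genome_read(small_fixture):
    fx = small_fixture
    read = fx.genome[0].sequence[40_000:42_000]
    assert not tdna_containment(read, fx.vector.sequence)


def test_containment_accepts_200bp_vector_fragment(small_fixture):
    fx = small_fixture
    read = (
        fx.genome[0].sequence[40_000:41_000]
        + fx.vector.sequence[5000:5200]
        + fx.genome[0].sequence[45_000:46_000]
    )
    assert tdna_containment(read, fx.vector.sequence)


def test_containment_respects_min_hits_threshold(small_fixture):
    fx = small_fixture
    read = fx.genome[0].sequence[40_000:41_000] + fx.vector.sequence[5000:5021]
    # exactly one shared 21-mer
    assert not tdna_containment(read, fx.vector.sequence, min_hits=5)
    assert tdna_containment(read, fx.vector.sequence, min_hits=1)


def test_containment_detects_reverse_complement(small_fixture):
    fx = small_fixture
    read = revcomp(fx.vector.sequence[5000:5300])
    assert tdna_containment(read, fx.vector.sequence)


# ------------------------------------------------------------ resolution


def _spanning_reads(fx, event, contig_idx, n=4, half=3000):
    """Error-free corrected reads spanning the event (mutant substrings)."""
    from tdnascout.junctions import CorrectedLongRead

    mut = fx.mutant[contig_idx].sequence
    # mutant coordinate of the left junction
    left = event.del_start - 1
    reads = []
    for i in range(n):
        lo = max(0, left - half - 211 * i)
        hi = min(len(mut), left + event.v_len + half + 173 * i)
        seq = mut[lo:hi] if i % 2 == 0 else revcomp(mut[lo:hi])
        reads.append(CorrectedLongRead(f"lr{i}", seq, 1.0, contains_tdna=True))
    return reads


def test_resolution_exact_on_error_free_reads(small_fixture):
    fx = small_fixture
    e = fx.events[0]
    site = CandidateSite("contig1", e.del_start - 200, e.del_start + 200)
    reads = _spanning_reads(fx, e, 0)
    call = resolve_breakpoints(
        site, reads, {c.id: c.sequence for c in fx.genome}, fx.vector.sequence
    )
    assert call.status == "confirmed"
    assert (call.del_start, call.del_end) == (e.del_start, e.del_end)
    assert (call.v_start, call.v_end) == (e.v_start, e.v_end)
    assert call.orientation == e.orientation
    assert call.breakpoint_ci == 0
    assert call.del_len == call.del_end - call.del_start + 1
    assert call.v_len == call.v_end - call.v_start + 1


def test_resolution_minus_orientation_event(small_fixture):
    """The reverse-orientation event: each junction is recovered one-sided
    and the merge reconstitutes the full call with the exact vector
    interval."""
    fx = small_fixture
    e = fx.events[1]
    genome = {c.id: c.sequence for c in fx.genome}
    mut = fx.mutant[1].sequence
    from tdnascout.junctions import CorrectedLongRead

    left = e.del_start - 1  # mutant coord of last left-flank base
    right = left + e.v_len  # mutant coord of last inserted base
    left_reads = [
        CorrectedLongRead(f"l{i}", mut[left - 3000 - 7 * i : left + 3000], 1.0, True)
        for i in range(3)
    ]
    right_reads = [
        CorrectedLongRead(f"r{i}", mut[right - 3000 : right + 3000 + 7 * i], 1.0, True)
        for i in range(3)
    ]
    site_l = CandidateSite("contig2", e.del_start - 200, e.del_start + 10)
    site_r = CandidateSite("contig2", e.del_end - 10, e.del_end + 200)
    call_l = resolve_breakpoints(site_l, left_reads, genome, fx.vector.sequence)
    call_r = resolve_breakpoints(site_r, right_reads, genome, fx.vector.sequence)
    assert call_l.junctions_observed == ("left",)
    assert call_r.junctions_observed == ("right",)
    (merged,) = merge_one_sided_calls([call_l, call_r])
    assert merged.status == "confirmed"
    assert (merged.del_start, merged.del_end) == (e.del_start, e.del_end)
    assert (merged.v_start, merged.v_end) == (e.v_start, e.v_end)
    assert merged.orientation == "-"


def test_pairs_only_site_stays_candidate(small_fixture):
    fx = small_fixture
    site = CandidateSite(
        "contig1", 5000, 5400,
        pairs=[DiscordantPair("p", ("contig1", 5100, "+"), (1, "+"))],
    )
    call = resolve_breakpoints(
        site, [], {c.id: c.sequence for c in fx.genome}, fx.vector.sequence
    )
    assert call.status == "candidate"
    assert call.v_start is None and call.v_end is None
    assert call.orientation is None


def test_decoy_site_reads_all_excluded_by_containment(small_fixture):
    """Long reads extracted at a site without any true event contain no
    vector sequence: the containment filter rejects every one and the site
    cannot be confirmed."""
    fx = small_fixture
    decoy = CandidateSite("contig1", 45_000, 45_400)
    reads = simgen.simulate_long_reads(
        fx.mutant, simgen.LongReadParams(depth=3, seed=19)
    )
    composite = fx.genome + [fx.vector]
    params = litemap.MapParams.long_read()
    idx = litemap.build_index(composite, params)
    alns = [litemap.map_read(r.sequence, idx, composite, params, read_id=r.id)[0]
            for r in reads]
    ids = extract_target_longreads(alns, [decoy], flank=2000)
    assert ids  # the decoy does attract overlapping reads
    by_id = {r.id: r for r in reads}
    corrected = correct_longreads([by_id[i] for i in sorted(ids)], [])
    for c in corrected:
        c.contains_tdna = tdna_containment(c.sequence, fx.vector.sequence)
    assert not any(c.contains_tdna for c in corrected)
    call = resolve_breakpoints(
        decoy, corrected, {c.id: c.sequence for c in fx.genome}, fx.vector.sequence
    )
    assert call.status == "candidate"  # never confirmed


def test_merge_leaves_two_sided_calls_alone():
    a = EventCall("c1", 100, 470, 10, 397, "+", status="confirmed",
                  junctions_observed=("left", "right"))
    b = EventCall("c2", 900, 1100, 50, 200, "-", status="confirmed",
                  junctions_observed=("left", "right"))
    assert merge_one_sided_calls([a, b]) == [a, b]


# ------------------------------------------------------------ QC


def test_qc_all_unmapped():
    alns = [AlnRecord("r", None, 0, "+", [], unmapped=True) for _ in range(5)]
    fq = [FastqRecord(f"r{i}", "ACGT", (30,) * 4) for i in range(5)]
    refs = [SeqRecord("c1", "A" * 1000)]
    qc = qc_summary(alns, fq, refs)
    assert qc["mapped_fraction"] == 0.0
    assert qc["q30_fraction"] == 1.0


def test_qc_depth_arithmetic():
    # 15,000 fragments of 2 x 100 bp fully aligned over 100 kb -> 30x
    alns = [_aln(pos=1, qid=f"r{i}", seq=None) for i in range(30_000)]
    fq = [FastqRecord(f"r{i}", "A" * 100, (30,) * 100) for i in range(30_000)]
    refs = [SeqRecord("c1", "A" * 100_000)]
    qc = qc_summary(alns, fq, refs)
    assert qc["mean_depth"] == pytest.approx(30.0)
    assert qc["mean_read_len"] == 100.0
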