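"""Synthetic-data generator: determinism, composition, event arithmetic,
read-origin oracles."""

import math

import pytest

from tdnascout import simgen
from tdnascout.io_formats import EventRecord, read_events_bed, read_events_json, revcomp
from tdnascout.simgen import (
    LongReadParams,
    ShortReadParams,
    VectorSpec,
    apply_events,
    emit_truth,
    simulate_genome,
    simulate_long_reads,
    simulate_short_reads,
    simulate_vector,
)


# ---------------------------------------------------------------- genome


def test_genome_deterministic_given_seed():
    a = simulate_genome(1, [1000], 0.5, seed=7)
    b = simulate_genome(1, [1000], 0.5, seed=7)
    assert a == b


def test_genome_degenerate_gc_one_is_pure_gc():
    (rec,) = simulate_genome(1, [500], 1.0, seed=1)
    assert set(rec.sequence) <= {"G", "C"}


def test_genome_gc_within_binomial_bound():
    contigs = simulate_genome(2, [50_000, 50_000], 0.36, seed=1)
    for c in contigs:
        gc = sum(1 for ch in c.sequence if ch in "GC") / len(c)
        assert 0.33 <= gc <= 0.39


def test_genome_rejects_bad_length():
    with pytest.raises(ValueError):
        simulate_genome(1, [0], 0.5, seed=1)


# ---------------------------------------------------------------- vector


def test_vector_length_and_determinism():
    spec = VectorSpec(length=12_000, cassette_start=3000, cassette_end=11_000,
                      transgene_start=5000, transgene_end=6088)
    a = simulate_vector(spec, seed=3)
    b = simulate_vector(spec, seed=3)
    assert len(a) == 12_000 and a == b


def test_vector_default_transgene_is_1089_bp():
    assert VectorSpec().transgene_len == 1089


def test_vector_intervals_must_nest():
    with pytest.raises(ValueError):
        VectorSpec(length=5000, cassette_start=100, cassette_end=400,
                   transgene_start=300, transgene_end=600)


# ------------------------------------------------------------ apply_events


def test_zero_events_is_identity():
    genome = simulate_genome(1, [10_000], 0.4, seed=2)
    vector = simulate_vector(VectorSpec(), seed=3)
    mutant, cmap = apply_events(genome, vector, [])
    assert mutant == genome
    assert cmap.lift("contig1", 1234) == 1234


@pytest.mark.parametrize(
    "v_len,del_len,delta",
    [(388, 371, 17), (8159, 48_988, -40_829)],
)
def test_event_length_balance(v_len, del_len, delta):
    genome = simulate_genome(1, [60_000], 0.4, seed=2)
    vector = simulate_vector(VectorSpec(), seed=3)
    e = EventRecord("contig1", 5000, 5000 + del_len - 1, 100, 100 + v_len - 1, "+", "e")
    mutant, _ = apply_events(genome, vector, [e])
    assert len(mutant[0]) - len(genome[0]) == delta


def test_minus_orientation_inserts_reverse_complement():
    genome = simulate_genome(1, [2000], 0.4, seed=2)
    vector = simulate_vector(VectorSpec(length=600, cassette_start=10,
                                        cassette_end=590, transgene_start=100,
                                        transgene_end=200, lb_pos=5, rb_pos=595), seed=3)
    e = EventRecord("contig1", 1001, 1000, 50, 149, "-", "ins")  # pure insertion
    mutant, _ = apply_events(genome, vector, [e])
    inserted = mutant[0].sequence[1000:1100]
    assert inserted == revcomp(vector.sequence[49:149])


def test_deleted_substring_absent_from_mutant(small_fixture):
    fx = small_fixture
    by_id = {c.id: c for c in fx.genome}
    mut_by_id = {c.id: c for c in fx.mutant}
    for e in fx.events:
        deleted = by_id[e.chrom].sequence[e.del_start - 1 : e.del_end]
        assert deleted not in mut_by_id[e.chrom].sequence


def test_overlapping_events_rejected():
    genome = simulate_genome(1, [10_000], 0.4, seed=2)
    vector = simulate_vector(VectorSpec(), seed=3)
    evs = [
        EventRecord("contig1", 1000, 2000, 1, 100, "+", "a"),
        EventRecord("contig1", 1500, 2500, 1, 100, "+", "b"),
    ]
    with pytest.raises(ValueError, match="overlap"):
        apply_events(genome, vector, evs)


def test_event_outside_contig_rejected():
    genome = simulate_genome(1, [1000], 0.4, seed=2)
    vector = simulate_vector(VectorSpec(), seed=3)
    with pytest.raises(ValueError, match="outside"):
        apply_events(genome, vector, [EventRecord("contig1", 900, 1100, 1, 50, "+", "x")])


def test_coordinate_map_lift_reproduces_reference_bases(small_fixture):
    fx = small_fixture
    by_id = {c.id: c for c in fx.genome}
    mut_by_id = {c.id: c for c in fx.mutant}
    for chrom in ("contig1", "contig2"):
        ref = by_id[chrom].sequence
        mut = mut_by_id[chrom].sequence
        for pos in range(1, len(ref) + 1, 997):
            lifted = fx.coord_map.lift(chrom, pos)
            if lifted is None:
                continue  # deleted position, has no image
            assert mut[lifted - 1] == ref[pos - 1]


# ------------------------------------------------------------ short reads


def test_short_read_fragment_count_formula():
    genome = simulate_genome(1, [100_000], 0.4, seed=4)
    params = ShortReadParams(depth=30, read_len=100, sub_rate=0.0, seed=5)
    r1, r2 = simulate_short_reads(genome, params)
    assert len(r1) == len(r2) == math.ceil(30 * 100_000 / 200)


def test_error_free_short_reads_are_exact_substrings():
    genome = simulate_genome(1, [20_000], 0.4, seed=4)
    seq = genome[0].sequence
    r1, r2 = simulate_short_reads(genome, ShortReadParams(depth=2, sub_rate=0.0, seed=5))
    for rec in list(r1)[:200] + list(r2)[:200]:
        assert rec.sequence in seq or revcomp(rec.sequence) in seq


def test_short_reads_deterministic():
    genome = simulate_genome(1, [20_000], 0.4, seed=4)
    p = ShortReadParams(depth=2, seed=9)
    assert simulate_short_reads(genome, p) == simulate_short_reads(genome, p)


def test_insert_longer_than_contig_rejected():
    genome = simulate_genome(1, [300], 0.4, seed=4)
    with pytest.raises(ValueError, match="insert_mean"):
        simulate_short_reads(genome, ShortReadParams(depth=1, seed=1))


# ------------------------------------------------------------ long reads


def test_error_free_long_reads_match_encoded_origin():
    genome = simulate_genome(1, [40_000], 0.4, seed=6)
    seq = genome[0].sequence
    reads = simulate_long_reads(
        genome, LongReadParams(depth=3, sub_rate=0, ins_rate=0, del_rate=0, seed=7)
    )
    assert reads
    for r in reads:
        _, contig, start, strand = r.id.split("/")
        span = seq[int(start) - 1 : int(start) - 1 + len(r.sequence)]
        assert r.sequence == (span if strand == "+" else revcomp(span))


def test_long_read_mean_length_within_15_percent():
    genome = simulate_genome(1, [50_000], 0.4, seed=6)
    mu = math.log(2000) - 0.25**2 / 2  # target mean 2 kb
    params = LongReadParams(
        len_mean_log=mu, len_sd_log=0.25, depth=10,
        sub_rate=0, ins_rate=0, del_rate=0, seed=8,
    )
    reads = simulate_long_reads(genome, params)
    assert len(reads) >= 200
    mean_len = sum(len(r.sequence) for r in reads) / len(reads)
    assert abs(mean_len - 2000) / 2000 < 0.15


def test_long_read_error_process_length_effects():
    import numpy as np

    from tdnascout.simgen import _mutate_long

    frag = simulate_genome(1, [3000], 0.4, seed=6)[0].sequence
    rng = np.random.default_rng(9)
    del_only = LongReadParams(sub_rate=0, ins_rate=0, del_rate=0.05)
    assert len(_mutate_long(frag, del_only, rng)) < len(frag)
    ins_only = LongReadParams(sub_rate=0, ins_rate=0.05, del_rate=0)
    assert len(_mutate_long(frag, ins_only, rng)) > len(frag)
    sub_only = LongReadParams(sub_rate=0.05, ins_rate=0, del_rate=0)
    mutated = _mutate_long(frag, sub_only, rng)
    assert len(mutated) == len(frag) and mutated != frag


# ------------------------------------------------------------ truth files


def test_emit_truth_round_trip(tmp_path):
    events = [
        EventRecord("c1", 100, 470, 10, 397, "+", "a"),
        EventRecord("c2", 900, 1100, 50, 200, "-", "b"),
    ]
    jpath, bpath = emit_truth(events, tmp_path / "truth")
    assert read_events_json(jpath) == events
    bed = read_events_bed(bpath)
    assert len(bed) == 2
    assert [e.label for e in bed] == ["a", "b"]


def test_emit_truth_empty_event_list(tmp_path):
    jpath, bpath = emit_truth([], tmp_path / "truth")
    assert read_events_json(jpath) == []
    assert bpath.read_text() == ""


# ------------------------------------------------------------ fixture


def test_default_fixture_mirrors_published_geometry(default_fixture):
    fx = default_fixture
    small, large = fx.events
    assert (small.del_len, small.v_len) == (371, 388)
    assert (large.del_len, large.v_len) == (48_988, 8159)
    assert {small.orientation, large.orientation} == {"+", "-"}
    assert len(fx.mutant[0]) == len(fx.genome[0]) + 17
    assert len(fx.mutant[1]) == len(fx.genome[1]) - 40_829


def test_default_fixture_junctions_identifiable(default_fixture):
    from tdnascout.simgen import _junction_identifiable

    fx = default_fixture
    by_id = {c.id: c for c in fx.genome}
    for e in fx.events:
        assert _junction_identifiable(by_id[e.chrom].sequence, fx.vector.sequence, e)
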