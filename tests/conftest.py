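"""Shared fixtures.

The expensive end-to-end pipeline runs (default two-event scenario at full
depth, with and without sequencing errors) are session-scoped so every test
that needs them shares one run.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from tdnascout import pipeline, simgen

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_fixture() -> simgen.Fixture:
    """The default two-event scenario (200 kb + 120 kb contigs)."""
    return simgen.two_event_fixture()


@pytest.fixture(scope="session")
def small_fixture() -> simgen.Fixture:
    """A scaled-down two-event scenario for fast unit tests."""
    from tdnascout.io_formats import EventRecord
    from tdnascout.simgen import (
        VectorSpec,
        _place_identifiable,
        apply_events,
        simulate_genome,
        simulate_vector,
    )

    genome = simulate_genome(2, [60_000, 40_000], gc=0.36, seed=11)
    spec = VectorSpec()
    vector = simulate_vector(spec, seed=12)
    nominal = [
        EventRecord("contig1", 30_000, 30_370, 10_719, 11_106, "+", "small"),
        EventRecord("contig2", 10_001, 25_000, 3_967, 12_125, "-", "large"),
    ]
    by_id = {c.id: c for c in genome}
    events = [
        _place_identifiable(by_id[e.chrom].sequence, vector.sequence, e)
        for e in nominal
    ]
    mutant, cmap = apply_events(genome, vector, events)
    return simgen.Fixture(genome, vector, events, mutant, cmap, spec)


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> pipeline.RunReport:
    """Full pipeline on the default scenario with the default error rates."""
    outdir = tmp_path_factory.mktemp("noisy_run")
    cfg = pipeline.PipelineConfig(output_dir=str(outdir), seed=1)
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory) -> pipeline.RunReport:
    """Full pipeline on the default scenario with error-free reads."""
    outdir = tmp_path_factory.mktemp("clean_run")
    cfg = pipeline.PipelineConfig(
        output_dir=str(outdir),
        seed=1,
        short_sub_rate=0.0,
        long_error=(0.0, 0.0, 0.0),
    )
    return pipeline.run_pipeline(cfg)
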