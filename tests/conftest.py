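"""Shared fixtures: the textbook worked example and simulation helpers."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tracedup import (
    RunParameters,
    Trace,
    build_index,
    detect,
    generate_reference,
)
from tracedup.simulate import DuplicationSpec, SimulationConfig, generate_reads

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# Textbook example (k = 3): the read duplicates AGAT, giving the trace
# [3, 4, 5, -, -, 4, 5, 6, 7] with the positions going back across the break.
WORKED_REF = "TTGCAGATCC"
WORKED_READ = "CAGATAGATCC"
WORKED_TRACE = [3, 4, 5, None, None, 4, 5, 6, 7]


@pytest.fixture(scope="session")
def worked_index():
    return build_index(WORKED_REF, 3)


@pytest.fixture(scope="session")
def random_ref():
    return generate_reference(300, seed=7)


@pytest.fixture(scope="session")
def ref_index(random_ref):
    return build_index(random_ref, 12)


def make_trace(entries, k=3, read_seq="", read_id="t") -> Trace:
    """A trace already in the disambiguated state, for direct event calls."""
    return Trace(
        read_id=read_id,
        read_seq=read_seq or "N" * (len(entries) + k - 1),
        k=k,
        entries=list(entries),
        state="disambiguated",
    )


def run_simulation(
    *,
    duplications,
    n_reads,
    seed,
    reference_length=400,
    read_length=120,
    error_rate=0.0,
    params: RunParameters | None = None,
):
    """Simulate a read set and push it through the full detection pipeline."""
    config = SimulationConfig(
        reference_length=reference_length,
        duplications=[DuplicationSpec(*spec) for spec in duplications],
        read_length=read_length,
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
    )
    reference, reads = generate_reads(config)
    params = params or RunParameters()
    index = build_index(reference, params.k, params.bloom_fp_rate)
    result = detect(((r.read_id, r.sequence) for r in reads), index, params)
    return config, reference, reads, result
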