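"""Shared fixtures: one simulated study, mapped once, reused across tests."""

from __future__ import annotations

import pytest

from floret import mapping
from floret import simulate as sim


@pytest.fixture(scope="session")
def study():
    """Default synthetic two-library EST study (noise-free)."""
    return sim.simulate_study(sim.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def read_triples(study):
    return [
        (rid, lib, seq) for lib in ("G", "H") for rid, seq in study.reads[lib]
    ]


@pytest.fixture(scope="session")
def assignments(study, read_triples):
    assigned, unmapped = mapping.map_reads(read_triples, study.genome, study.genes)
    return assigned, unmapped


@pytest.fixture(scope="session")
def read_seqs(study):
    return {rid: seq for lib in ("G", "H") for rid, seq in study.reads[lib]}
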