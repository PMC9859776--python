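"""Shared fixtures: toy read libraries and one full default study per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridsip import RunConfig, run_study
from hybridsip import _codec
from hybridsip.sequencing import ReadLibrary

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_library(
    seqs: list[str],
    truth: list[str] | None = None,
    library_id: str = "pH4.5_12C_LBD_r1",
    soil: str = "pH4.5",
    treatment: str = "12C",
    pool: str = "LBD",
    replicate: int = 1,
) -> ReadLibrary:
    """Build a ReadLibrary from raw sequences (all the same length)."""
    truth = truth or ["unknown"] * len(seqs)
    pop_ids = sorted(set(truth))
    index = {p: i for i, p in enumerate(pop_ids)}
    read_length = len(seqs[0]) if seqs else 0
    reads = (
        np.stack([_codec.encode(s) for s in seqs])
        if seqs
        else np.empty((0, read_length), dtype=np.uint8)
    )
    return ReadLibrary(
        library_id=library_id,
        soil=soil,
        treatment=treatment,
        pool=pool,
        replicate=replicate,
        read_length=read_length,
        reads=reads,
        truth_pop=np.array([index[t] for t in truth], dtype=np.int64),
        truth_pop_ids=pop_ids,
    )


@pytest.fixture(scope="session")
def default_study():
    """One full default two-soil study (seeded); shared across tests."""
    return run_study(RunConfig(master_seed=1))


@pytest.fixture()
def small_config() -> RunConfig:
    """A cheap configuration for end-to-end plumbing tests."""
    cfg = RunConfig(master_seed=7)
    cfg.sequencing.depth = 4_000
    return cfg
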