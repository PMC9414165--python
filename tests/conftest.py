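"""Shared fixtures: synthetic pore models, genome, reads and BAM fixture."""

from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from teloscan import (
    SyntheticReadSpec,
    make_genome,
    simulate_reads,
    synthetic_pore_model,
    write_fixture_bam,
)

# location where the published ONT r9.4 180mV 450bps 6-mer level table is
# expected when available (see README for the download source); checks that
# reproduce its printed statistics require the real table, not a stand-in
REAL_MODEL_PATH = Path(__file__).resolve().parents[1] / "data" / "r9.4_180mv_450bps_6mer.model"


@pytest.fixture(scope="session")
def model6():
    return synthetic_pore_model(k=6, seed=1)


@pytest.fixture(scope="session")
def model4():
    return synthetic_pore_model(k=4, seed=3)


@pytest.fixture(scope="session")
def model2():
    return synthetic_pore_model(k=2, seed=7)


@pytest.fixture(scope="session")
def genome():
    return make_genome(n_chrom=2, arm_tract=3_000, core_len=50_000, seed=1)


@pytest.fixture(scope="session")
def sim_reads(genome):
    return simulate_reads(genome, SyntheticReadSpec(n_reads=60, seed=2))


@pytest.fixture(scope="session")
def fixture_bam(genome, sim_reads, tmp_path_factory):
    path = tmp_path_factory.mktemp("bam") / "fixture.bam"
    return str(write_fixture_bam(sim_reads, genome, path))
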