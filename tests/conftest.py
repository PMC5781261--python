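"""Shared fixtures: small deterministic communities plus the standard
benchmark runs used by the acceptance-level tests (session-scoped, so the
expensive 200k-read workflow executes once)."""

from dataclasses import dataclass

import numpy as np
import pytest

from spherical import _encode
from spherical.align import AlignParams
from spherical.assemble import AssemblerParams
from spherical.io_seq import Read
from spherical.simulate import CommunitySpec, simulate_community
from spherical.workflow import WorkflowConfig, run

BENCHMARK_SEED = 101
RUN_SEED = 7


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _encode.decode_codes(rng.integers(0, 4, n).astype(np.uint8))


@pytest.fixture(scope="session")
def small_truth():
    """4 genomes, 20k x 80 bp reads, 1% error: fast end-to-end fixture."""
    spec = CommunitySpec(
        n_genomes=4,
        genome_length=(2000, 3000),
        total_reads=20_000,
        read_length=80,
        error_rate=0.01,
        seed=11,
    )
    return simulate_community(spec)


@pytest.fixture(scope="session")
def benchmark_truth():
    """The standard benchmark community (generator defaults)."""
    return simulate_community(CommunitySpec(seed=BENCHMARK_SEED))


@dataclass
class BenchmarkRuns:
    truth: object
    spherical: object  # 3 iterations, full data each round
    base: object  # single-pass comparator
    quarter: object  # 3 iterations on 25% subsamples


@pytest.fixture(scope="session")
def benchmark_runs(benchmark_truth):
    """Iterative vs single-pass vs subsampled runs on the benchmark."""
    common = dict(align_threshold_pct=100.0, seed=RUN_SEED)
    spherical = run(
        benchmark_truth.reads,
        WorkflowConfig(subsample_fractions=1.0, max_iterations=3, **common),
    )
    base = run(
        benchmark_truth.reads,
        WorkflowConfig(subsample_fractions=1.0, max_iterations=1, **common),
    )
    quarter = run(
        benchmark_truth.reads,
        WorkflowConfig(subsample_fractions=0.25, max_iterations=3, **common),
    )
    return BenchmarkRuns(
        truth=benchmark_truth, spherical=spherical, base=base, quarter=quarter
    )


@pytest.fixture(scope="session")
def zero_error_run():
    """Single-pass assembly of an error-free community (quality limit)."""
    truth = simulate_community(
        CommunitySpec(total_reads=60_000, error_rate=0.0, seed=202)
    )
    result = run(
        truth.reads,
        WorkflowConfig(
            subsample_fractions=1.0,
            max_iterations=1,
            align_threshold_pct=100.0,
            seed=RUN_SEED,
        ),
    )
    return truth, result


def tile_reads(genome: str, read_len: int, stride: int = 1) -> list[Read]:
    """Stride-tiled error-free reads covering every kmer of a genome."""
    return [
        Read(id=f"t{i}", seq=genome[i : i + read_len])
        for i in range(0, len(genome) - read_len + 1, stride)
    ]
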