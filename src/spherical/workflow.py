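"""The iterative assembly engine.

Each round: draw a random subsample of the reads still unaligned, assemble
it, align *all* remaining reads (not only the subsample) to the new
contigs, and retire the ones that align — a read utilised once is never
re-tested. Rounds continue until an iteration cap, a target utilisation
percentage, exhaustion of the reads, or a stalled round (zero new reads
utilised; guards against unassemblable residue). Finally the per-iteration
assemblies are concatenated into a combined assembly, with an optional
re-assembly of the combined contigs themselves to join overlapping ends.

Subsampling reduces only the assembler's input (memory/time pressure);
the aligned/unaligned partition always covers every remaining read, so
utilisation accounting is exact regardless of the subsample fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import io_seq, metrics
from .align import AlignmentHit, AlignParams, coverage_profile, partition_reads
from .assemble import Assembly, AssemblerParams, get_backend
from .errors import AssemblyError, SphericalError
from .io_seq import Read


@dataclass
class WorkflowConfig:
    """Run options.

    ``subsample_fractions`` is a single fraction in (0, 1] or one per
    iteration (the last value repeats when the list runs out); 1 feeds the
    whole remaining set to the assembler. Defaults: 5 iterations or a 70%
    utilisation target, whichever comes first. ``min_kmer_cov='auto'``
    (coverage-adaptive cutoff) is the pipeline default because a fixed
    cutoff cannot follow the falling coverage of successive residues.
    """

    subsample_fractions: Union[float, Sequence[float]] = 1.0
    max_iterations: int = 5
    align_threshold_pct: float = 70.0
    assembler: str = "builtin"
    assembler_params: AssemblerParams = field(
        default_factory=lambda: AssemblerParams(min_kmer_cov="auto")
    )
    align_params: AlignParams = field(default_factory=AlignParams)
    seed: int = 0
    merge: bool = True
    final_reassembly: bool = False
    passthrough: Optional[str] = None

    def __post_init__(self) -> None:
        for f in self._fractions():
            if not (0 < f <= 1):
                raise ValueError(f"subsample fraction {f} outside (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 <= self.align_threshold_pct <= 100):
            raise ValueError("align_threshold_pct must be in [0, 100]")

    def _fractions(self) -> list[float]:
        if isinstance(self.subsample_fractions, (int, float)):
            return [float(self.subsample_fractions)]
        return [float(f) for f in self.subsample_fractions]


@dataclass
class IterationResult:
    """Outcome of one round."""

    iteration: int
    n_candidates: int
    n_subsampled: int
    assembly: Assembly
    hits: list[AlignmentHit]
    n_newly_aligned: int
    cumulative_aligned: int
    cumulative_utilisation_pct: float
    stats: metrics.AssemblyStats


@dataclass
class SphericalResult:
    """Everything one run produced."""

    iterations: list[IterationResult]
    combined_assembly: Assembly
    combined_stats: metrics.AssemblyStats
    final_assembly: Optional[Assembly]
    unaligned: list[Read]
    stop_reason: str
    n_input: int
    config: WorkflowConfig

    @property
    def utilisation_pct(self) -> float:
        if not self.iterations:
            return 0.0
        return self.iterations[-1].cumulative_utilisation_pct

    def all_hits(self) -> list[AlignmentHit]:
        return [h for it in self.iterations for h in it.hits]

    def hits_per_iteration(self) -> dict[int, list[AlignmentHit]]:
        return {it.iteration: it.hits for it in self.iterations}


def subsample(
    reads: Sequence[Read], fraction: float, rng: np.random.Generator
) -> list[Read]:
    """Simple random sample without replacement, size max(1, round(f*n)),
    input order preserved. fraction == 1 returns the full set and draws
    nothing from the RNG."""
    if not reads:
        raise SphericalError("cannot subsample an empty read set")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if fraction == 1:
        return list(reads)
    size = max(1, round(fraction * len(reads)))
    idx = rng.choice(len(reads), size=size, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def fraction_for_iteration(config: WorkflowConfig, i: int) -> float:
    """The i-th (1-based) subsample fraction; the last listed value
    repeats beyond the end of the list."""
    if i < 1:
        raise ValueError("iteration index is 1-based")
    fractions = config._fractions()
    return fractions[min(i, len(fractions)) - 1]


def run_iteration(
    candidates: Sequence[Read],
    config: WorkflowConfig,
    iteration: int,
    rng: np.random.Generator,
    n_input: int,
    already_aligned: int,
) -> tuple[IterationResult, list[Read]]:
    """One round: subsample -> assemble -> partition all candidates."""
    if not candidates:
        raise SphericalError("run_iteration called with no candidate reads")
    fraction = fraction_for_iteration(config, iteration)
    sub = subsample(candidates, fraction, rng)
    backend = get_backend(config.assembler)
    try:
        assembly = backend(sub, config.assembler_params).tag_iteration(iteration)
    except AssemblyError:
        assembly = Assembly(
            contigs=[], k=config.assembler_params.k, backend=config.assembler,
            iteration=iteration,
        )
    hits, unaligned = partition_reads(
        candidates, assembly.contigs, config.align_params
    )
    assert len(hits) + len(unaligned) == len(candidates)
    cum = already_aligned + len(hits)
    cov = (
        coverage_profile(assembly.contigs, hits) if assembly.contigs else None
    )
    stats = metrics.assembly_stats(
        assembly, n_aligned=cum, input_total=n_input, coverage=cov
    )
    result = IterationResult(
        iteration=iteration,
        n_candidates=len(candidates),
        n_subsampled=len(sub),
        assembly=assembly,
        hits=hits,
        n_newly_aligned=len(hits),
        cumulative_aligned=cum,
        cumulative_utilisation_pct=metrics.alignment_rate(cum, n_input),
        stats=stats,
    )
    return result, unaligned


def should_stop(
    iterations: Sequence[IterationResult],
    n_remaining: int,
    config: WorkflowConfig,
) -> Optional[str]:
    """Stop reason after >= 1 completed iteration, or None to continue."""
    if not iterations:
        raise ValueError("should_stop needs at least one completed iteration")
    last = iterations[-1]
    if last.cumulative_utilisation_pct >= config.align_threshold_pct:
        return "align_threshold"
    if len(iterations) >= config.max_iterations:
        return "max_iterations"
    if n_remaining == 0:
        return "all_reads_utilised"
    if last.n_newly_aligned == 0:
        return "stalled"
    return None


def merge_assemblies(assemblies: Sequence[Assembly]) -> Assembly:
    """Concatenate per-iteration assemblies; no deduplication. Contig ids
    already carry their ``it<I>_`` prefix; a collision is an error."""
    if not assemblies:
        raise SphericalError("nothing to merge")
    contigs = [c for a in assemblies for c in a.contigs]
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise SphericalError("contig id collision while merging assemblies")
    return Assembly(
        contigs=contigs,
        k=assemblies[0].k,
        backend=assemblies[0].backend,
        iteration=None,
    )


def final_reassembly(combined: Assembly, config: WorkflowConfig) -> Assembly:
    """Re-assemble the combined contigs themselves (same k) to join
    overlapping ends. Every kmer occurs once per contig, so the coverage
    cutoff is forced to 1."""
    if not combined.contigs:
        raise SphericalError("cannot re-assemble an empty combined assembly")
    params = replace(
        config.assembler_params, min_kmer_cov=1, min_contig_len=config.assembler_params.k
    )
    pseudo_reads = [Read(id=c.id, seq=c.seq) for c in combined.contigs]
    backend = get_backend(config.assembler)
    assembly = backend(pseudo_reads, params)
    return Assembly(
        contigs=assembly.contigs, k=assembly.k, backend=assembly.backend,
        iteration=None,
    )


def run(reads: Sequence[Read], config: WorkflowConfig) -> SphericalResult:
    """Run the full iterative workflow. Deterministic given config.seed."""
    reads = list(reads)
    if not reads:
        raise SphericalError("no input reads")
    n_input = len(reads)
    rng = np.random.default_rng(config.seed)
    candidates = reads
    iterations: list[IterationResult] = []
    cum = 0
    stop = None
    for i in range(1, config.max_iterations + 1):
        result, candidates = run_iteration(
            candidates, config, i, rng, n_input, cum
        )
        cum = result.cumulative_aligned
        iterations.append(result)
        stop = should_stop(iterations, len(candidates), config)
        if stop:
            break
    assert stop is not None
    # read conservation across the whole run
    assert sum(it.n_newly_aligned for it in iterations) + len(candidates) == n_input
    utilised_ids = [h.read_id for it in iterations for h in it.hits]
    assert len(set(utilised_ids)) == len(utilised_ids), "read utilised twice"

    combined = merge_assemblies([it.assembly for it in iterations])
    all_hits = [h for it in iterations for h in it.hits]
    cov = coverage_profile(combined.contigs, all_hits) if combined.contigs else None
    combined_stats = metrics.assembly_stats(
        combined, n_aligned=cum, input_total=n_input, coverage=cov
    )
    final = None
    if config.final_reassembly and combined.contigs:
        final = final_reassembly(combined, config)
    return SphericalResult(
        iterations=iterations,
        combined_assembly=combined,
        combined_stats=combined_stats,
        final_assembly=final,
        unaligned=candidates,
        stop_reason=stop,
        n_input=n_input,
        config=config,
    )


def write_outputs(result: SphericalResult, out_dir) -> dict[str, str]:
    """Write per-iteration FASTA, combined (and final) FASTA, residue
    FASTQ and stats.json under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for it in result.iterations:
        p = out / f"iteration_{it.iteration}.fasta"
        io_seq.write_fasta(it.assembly.contigs, p)
        paths[f"iteration_{it.iteration}"] = str(p)
    p = out / "combined.fasta"
    io_seq.write_fasta(result.combined_assembly.contigs, p)
    paths["combined"] = str(p)
    if result.final_assembly is not None:
        p = out / "final.fasta"
        io_seq.write_fasta(result.final_assembly.contigs, p)
        paths["final"] = str(p)
    p = out / "unaligned.fastq"
    io_seq.write_fastq(result.unaligned, p)
    paths["unaligned"] = str(p)
    p = out / "stats.json"
    with open(p, "w") as fh:
        json.dump(stats_payload(result), fh, indent=2, sort_keys=True)
    paths["stats"] = str(p)
    return paths


def stats_payload(result: SphericalResult) -> dict:
    """JSON-ready per-iteration + combined statistics (no timings, so the
    payload is byte-stable under a fixed seed)."""
    return {
        "n_input_reads": result.n_input,
        "stop_reason": result.stop_reason,
        "utilisation_pct": round(result.utilisation_pct, 4),
        "iterations": {
            str(it.iteration): {
                "n_candidates": it.n_candidates,
                "n_subsampled": it.n_subsampled,
                "n_contigs": len(it.assembly.contigs),
                "n_newly_aligned": it.n_newly_aligned,
                "cumulative_aligned": it.cumulative_aligned,
                "cumulative_utilisation_pct": round(
                    it.cumulative_utilisation_pct, 4
                ),
                "stats": it.stats.to_dict(),
            }
            for it in result.iterations
        },
        "combined": result.combined_stats.to_dict(),
        "final": (
            {
                "n_contigs": len(result.final_assembly.contigs),
                "total_bp": result.final_assembly.total_bp,
            }
            if result.final_assembly is not None
            else None
        ),
    }
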