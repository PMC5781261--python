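"""Synthetic metagenome communities with truth labels.

Emulates, at desk scale, the kind of simulated benchmark used to validate
iterative assembly: many species at uneven abundance, one genome per
species, reads drawn in proportion to abundance with i.i.d. substitution
errors. Defaults describe the package's standard benchmark community:
20 uniform-random genomes of 5--10 kb, a linear abundance gradient with
the extremes in a 0.66% : 0.22% ratio (renormalised), 200,000 single-end
100 bp reads, 1% per-base substitution error.

The error model is substitution-only (the built-in aligner is ungapped);
strand is chosen uniformly; read ids encode the source genome and an
ordinal so truth survives FASTA round trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from . import _encode
from .io_seq import Read

LengthSpec = Union[int, tuple[int, int]]


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    ``abundance_max``/``abundance_min`` set the pre-normalisation extremes
    of a linear rank gradient; only their ratio matters after
    renormalisation.
    """

    n_genomes: int = 20
    genome_length: LengthSpec = (5000, 10000)
    abundance_max: float = 0.0066
    abundance_min: float = 0.0022
    total_reads: int = 200_000
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not (0 < self.abundance_min <= self.abundance_max):
            raise ValueError("need abundance_max >= abundance_min > 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        lo, hi = self._length_range()
        if lo < self.read_length:
            raise ValueError(
                f"genome_length {lo} shorter than read_length {self.read_length}"
            )

    def _length_range(self) -> tuple[int, int]:
        if isinstance(self.genome_length, int):
            return self.genome_length, self.genome_length
        lo, hi = self.genome_length
        if lo > hi:
            raise ValueError("genome_length range must be (min, max)")
        return lo, hi


@dataclass
class TruthSet:
    """Genomes, abundances and truth-labeled reads of one simulation."""

    genomes: list[tuple[str, str]]
    abundances: np.ndarray
    reads: list[Read]

    def truth_labels(self) -> dict[str, str]:
        """read id -> source genome id."""
        return {r.id: r.taxon for r in self.reads if r.taxon is not None}


def generate_genomes(spec: CommunitySpec) -> list[tuple[str, str]]:
    """i.i.d. uniform-random genomes; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec._length_range()
    width = max(2, len(str(spec.n_genomes)))
    genomes = []
    for i in range(spec.n_genomes):
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        genomes.append((f"g{i + 1:0{width}d}", _encode.decode_codes(codes)))
    return genomes


def assign_abundances(spec: CommunitySpec) -> np.ndarray:
    """Linear rank gradient from abundance_max down to abundance_min,
    renormalised to sum to 1."""
    if spec.n_genomes == 1:
        return np.array([1.0])
    raw = np.linspace(spec.abundance_max, spec.abundance_min, spec.n_genomes)
    return raw / raw.sum()


def assign_abundances_loguniform(spec: CommunitySpec) -> np.ndarray:
    """Alternative profile: log-spaced gradient between the same extremes."""
    if spec.n_genomes == 1:
        return np.array([1.0])
    raw = np.geomspace(spec.abundance_max, spec.abundance_min, spec.n_genomes)
    return raw / raw.sum()


def simulate_reads(
    genomes: Sequence[tuple[str, str]],
    abundances: np.ndarray,
    spec: CommunitySpec,
) -> TruthSet:
    """Draw reads: genome ~ abundance, start uniform, strand uniform,
    substitutions i.i.d. at ``error_rate``. Fully vectorised."""
    if len(genomes) != len(abundances):
        raise ValueError("genomes and abundances length mismatch")
    L = spec.read_length
    for gid, seq in genomes:
        if len(seq) < L:
            raise ValueError(f"genome {gid} shorter than read_length {L}")
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.total_reads
    p = np.asarray(abundances, dtype=float)
    p = p / p.sum()
    gidx = rng.choice(len(genomes), size=n, p=p)
    glens = np.array([len(seq) for _, seq in genomes])
    starts = (rng.random(n) * (glens[gidx] - L + 1)).astype(np.int64)
    minus = rng.random(n) < 0.5

    mat = np.empty((n, L), dtype=np.uint8)
    offsets = np.arange(L)
    for g in range(len(genomes)):
        rows = np.nonzero(gidx == g)[0]
        if rows.size == 0:
            continue
        gcodes = _encode.encode_seq(genomes[g][1])
        mat[rows] = gcodes[starts[rows, None] + offsets[None, :]]

    if minus.any():
        sub = mat[minus]
        mat[minus] = (3 - sub)[:, ::-1]

    if spec.error_rate > 0:
        errs = rng.random((n, L)) < spec.error_rate
        shift = rng.integers(1, 4, size=int(errs.sum()), dtype=np.uint8)
        mat[errs] = (mat[errs] + shift) % 4

    seq_str = _encode._DECODE[mat].tobytes().decode("ascii")
    ordinal_width = len(str(n))
    reads = []
    for i in range(n):
        gid = genomes[gidx[i]][0]
        reads.append(
            Read(
                id=f"{gid}_r{i:0{ordinal_width}d}",
                seq=seq_str[i * L : (i + 1) * L],
                taxon=gid,
            )
        )
    return TruthSet(genomes=list(genomes), abundances=p, reads=reads)


def simulate_community(
    spec: CommunitySpec, abundance_profile: str = "linear"
) -> TruthSet:
    """Convenience: genomes + abundances + reads in one call."""
    genomes = generate_genomes(spec)
    if abundance_profile == "linear":
        ab = assign_abundances(spec)
    elif abundance_profile == "loguniform":
        ab = assign_abundances_loguniform(spec)
    else:
        raise ValueError(f"unknown abundance profile {abundance_profile!r}")
    return simulate_reads(genomes, ab, spec)
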