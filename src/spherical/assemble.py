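"""Minimal deterministic de Bruijn unitig assembler and backend registry.

The iterative workflow treats the assembler as a pluggable black box; this
module provides a correct, byte-deterministic built-in: canonical-kmer de
Bruijn graph, coverage pruning, maximal non-branching (unitig) paths. No
bubble popping, no tip clipping, no scaffolding — misassembly-free output
matters more here than contiguity, because downstream statistics (false
base rate, contig score) assume every contig base is read-supported.

Coverage cutoff: ``min_kmer_cov`` may be an integer or ``"auto"``, in
which case the cutoff is half the coverage-weighted median kmer count
(the same heuristic assemblers use when asked to estimate expected
coverage themselves). The auto cutoff is what makes the workflow's core
behaviour visible on uneven communities: kmers of low-abundance genomes
fall below half of the community-wide expected coverage, their reads stay
unaligned, and later iterations recover them.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import _encode
from .errors import AssemblyError, BackendError
from .io_seq import Contig, Read


@dataclass
class AssemblerParams:
    """Built-in assembler knobs.

    k must be odd (no palindromic kmers). ``min_contig_len`` defaults to
    2k-1, i.e. at least k kmers per reported contig.
    """

    k: int = 31
    min_kmer_cov: Union[int, str] = 2
    min_contig_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 3")
        if isinstance(self.min_kmer_cov, str):
            if self.min_kmer_cov != "auto":
                raise ValueError("min_kmer_cov must be an integer >= 1 or 'auto'")
        elif self.min_kmer_cov < 1:
            raise ValueError("min_kmer_cov must be >= 1")

    @property
    def effective_min_contig_len(self) -> int:
        return self.min_contig_len if self.min_contig_len is not None else 2 * self.k - 1


_PACKED_K_MAX = 31  # 2-bit packing into uint64


def _canon_str(kmer: str) -> str:
    rc = _encode.revcomp_str(kmer)
    return kmer if kmer <= rc else rc


class DeBruijnGraph:
    """Canonical-kmer multiset with implicit (k-1)-overlap edges.

    For k <= 31 nodes live in a sorted uint64 array of canonical codes
    plus a parallel count array (the fast vectorised representation); for
    larger k they fall back to a canonical-string -> count dict. Edges are
    implied by kmer arithmetic in both modes.
    """

    def __init__(
        self,
        k: int,
        codes: Optional[np.ndarray] = None,
        counts: Optional[np.ndarray] = None,
        str_counts: Optional[dict[str, int]] = None,
    ):
        self.k = k
        if str_counts is not None:
            self.codes = None
            self.counts = None
            self.str_counts = str_counts
        else:
            self.codes = codes
            self.counts = counts
            self.str_counts = None

    @property
    def packed(self) -> bool:
        return self.str_counts is None

    def __len__(self) -> int:
        if self.packed:
            return len(self.codes)
        return len(self.str_counts)

    def __contains__(self, kmer: str) -> bool:
        return self.coverage(kmer) > 0

    def coverage(self, kmer: str) -> int:
        """Occurrence count of a kmer (canonical); 0 when absent."""
        if not self.packed:
            return self.str_counts.get(_canon_str(kmer.upper()), 0)
        code = _encode.kmer_to_code(kmer)
        canon = min(code, _encode.revcomp_code(code, self.k))
        i = int(np.searchsorted(self.codes, canon))
        if i < len(self.codes) and int(self.codes[i]) == canon:
            return int(self.counts[i])
        return 0

    def kmers(self) -> dict[str, int]:
        """Canonical kmer -> count as plain strings (small graphs only)."""
        if not self.packed:
            return dict(self.str_counts)
        return {
            _encode.code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }


def build_graph(reads: Sequence[Read], k: int) -> DeBruijnGraph:
    """Exact canonical kmer counts of all reads; kmers touching N skipped."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > _PACKED_K_MAX:
        counts: dict[str, int] = {}
        for r in reads:
            s = r.seq
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if any(b not in "ACGT" for b in w):
                    continue
                c = _canon_str(w)
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            raise AssemblyError(f"no usable kmers: no read contains a valid {k}-mer")
        return DeBruijnGraph(k, str_counts=counts)
    seqs = [r.seq for r in reads]
    mat, lengths = _encode.encode_matrix(seqs)
    canon, valid = _encode.canonical_kmer_matrix(mat, lengths, k)
    flat = canon[valid]
    if flat.size == 0:
        raise AssemblyError(f"no usable kmers: no read contains a valid {k}-mer")
    codes, counts_arr = np.unique(flat, return_counts=True)
    return DeBruijnGraph(k, codes, counts_arr.astype(np.int64))


def auto_cutoff(graph: DeBruijnGraph) -> int:
    """Velvet-style coverage cutoff: weighted-median kmer count / 2."""
    if graph.packed:
        counts = np.sort(graph.counts, kind="stable")
    else:
        counts = np.sort(np.fromiter(graph.str_counts.values(), dtype=np.int64))
    csum = np.cumsum(counts)
    half = csum[-1] / 2
    wm = int(counts[int(np.searchsorted(csum, half))])
    return max(2, wm // 2)


def prune(graph: DeBruijnGraph, min_kmer_cov: Union[int, str]) -> DeBruijnGraph:
    """Drop kmers below the coverage cutoff. Idempotent."""
    cutoff = auto_cutoff(graph) if min_kmer_cov == "auto" else int(min_kmer_cov)
    if cutoff < 1:
        raise ValueError("min_kmer_cov must be >= 1")
    if not graph.packed:
        kept = {w: n for w, n in graph.str_counts.items() if n >= cutoff}
        return DeBruijnGraph(graph.k, str_counts=kept)
    keep = graph.counts >= cutoff
    return DeBruijnGraph(graph.k, graph.codes[keep], graph.counts[keep])


def _adjacency(graph: DeBruijnGraph):
    """Precompute, for every node and orientation, the existing one-base
    extensions: existence mask, neighbor index and neighbor orientation.

    Orientation 0 walks the canonical spelling forward; orientation 1 walks
    the reverse-complement spelling forward.
    """
    k = graph.k
    codes = graph.codes
    n = len(codes)
    spell = np.empty((2, n), dtype=np.uint64)
    spell[0] = codes
    spell[1] = _encode.revcomp_codes(codes, k)
    mask = np.uint64((1 << (2 * (k - 1))) - 1)
    exists = np.zeros((2, 4, n), dtype=bool)
    nbr = np.zeros((2, 4, n), dtype=np.int64)
    nori = np.zeros((2, 4, n), dtype=np.int8)
    idx = np.arange(n)
    for o in (0, 1):
        for b in range(4):
            t = ((spell[o] & mask) << np.uint64(2)) | np.uint64(b)
            trc = _encode.revcomp_codes(t, k)
            tc = np.minimum(t, trc)
            pos = np.searchsorted(codes, tc)
            pos_c = np.minimum(pos, max(n - 1, 0))
            found = (pos < n) & (codes[pos_c] == tc) if n else np.zeros(0, bool)
            # a self-edge (hairpin fold onto the node's own reverse
            # complement, or a homopolymer loop) can never be walked by a
            # unitig, so it must not count towards branching degree
            found &= pos_c != idx
            exists[o, b] = found
            nbr[o, b] = pos_c
            nori[o, b] = np.where(t == tc, 0, 1)
    outdeg = exists.sum(axis=1).astype(np.int8)  # (2, n)
    return spell, exists, nbr, nori, outdeg


def _extract_unitigs_str(graph: DeBruijnGraph, min_contig_len: int) -> list[Contig]:
    """String-mode unitig walk (k > 31); same semantics as the packed path."""
    k = graph.k
    counts = graph.str_counts
    nodes = sorted(counts)

    def successors(node: str, orient: int) -> list[tuple[str, int, str]]:
        spelling = node if orient == 0 else _encode.revcomp_str(node)
        out = []
        for b in "ACGT":
            t = spelling[1:] + b
            tc = _canon_str(t)
            if tc in counts and tc != node:  # self-edges cannot be walked
                out.append((tc, 0 if t == tc else 1, b))
        return out

    deg: dict[tuple[str, int], list] = {}

    def succ(node: str, orient: int):
        key = (node, orient)
        if key not in deg:
            deg[key] = successors(node, orient)
        return deg[key]

    visited: set[str] = set()
    raw: list[tuple[str, float]] = []

    def walk(node: str, orient: int) -> tuple[str, float]:
        spelling = node if orient == 0 else _encode.revcomp_str(node)
        seq = list(spelling)
        cov = [counts[node]]
        visited.add(node)
        while True:
            nxt = succ(node, orient)
            if len(nxt) != 1:
                break
            j, o2, b = nxt[0]
            if len(succ(j, 1 - o2)) != 1:  # head in-degree
                break
            if j in visited:
                break
            seq.append(b)
            cov.append(counts[j])
            visited.add(j)
            node, orient = j, o2
        return "".join(seq), float(np.mean(cov))

    for node in nodes:
        if node in visited:
            continue
        for o in (0, 1):
            back = succ(node, 1 - o)
            if len(back) != 1:
                start = True
            else:
                j, o2, _b = back[0]
                start = len(succ(j, 1 - o2)) != 1
            if start:
                raw.append(walk(node, o))
                break
    for node in nodes:
        if node not in visited:
            raw.append(walk(node, 0))

    out = []
    for seq, cov in raw:
        if len(seq) < min_contig_len:
            continue
        out.append((min(seq, _encode.revcomp_str(seq)), cov))
    out.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(id=f"c{i + 1}_len{len(seq)}_cov{cov:.1f}", seq=seq, k=k, mean_cov=cov)
        for i, (seq, cov) in enumerate(out)
    ]


def extract_unitigs(graph: DeBruijnGraph, min_contig_len: int) -> list[Contig]:
    """Maximal non-branching paths of the (pruned) graph.

    A unitig extends across an edge only when the tail's out-degree and the
    head's in-degree are both exactly 1 — no greedy extension through
    branches. Output is sorted (length desc, sequence asc); each contig is
    emitted as the lexicographically smaller of its two spellings.
    """
    if not graph.packed:
        return _extract_unitigs_str(graph, min_contig_len)
    n = len(graph.codes)
    if n == 0:
        return []
    k = graph.k
    spell, exists, nbr, nori, outdeg = _adjacency(graph)
    counts = graph.counts
    visited = np.zeros(n, dtype=bool)
    raw: list[tuple[str, float]] = []

    def walk(i: int, o: int) -> tuple[str, float]:
        """Walk forward from oriented node (i, o); returns (seq, mean_cov)."""
        seq = bytearray(_encode.code_to_kmer(int(spell[o, i]), k), "ascii")
        cov = [int(counts[i])]
        visited[i] = True
        while True:
            if outdeg[o, i] != 1:
                break
            b = int(np.argmax(exists[o, :, i]))
            j = int(nbr[o, b, i])
            o2 = int(nori[o, b, i])
            # head's in-degree along this direction = out-degree of (j, 1-o2)
            if outdeg[1 - o2, j] != 1:
                break
            if visited[j]:
                break  # cycle closure or convergence with a prior unitig
            seq.append(b"ACGT"[b])
            cov.append(int(counts[j]))
            visited[j] = True
            i, o = j, o2
        return seq.decode("ascii"), float(np.mean(cov))

    for i in range(n):
        if visited[i]:
            continue
        for o in (0, 1):
            # (i, o) starts a unitig iff its incoming edge is absent or
            # unmergeable; incoming degree of (i, o) = outdeg of (i, 1-o).
            if outdeg[1 - o, i] != 1:
                start = True
            else:
                b = int(np.argmax(exists[1 - o, :, i]))
                j = int(nbr[1 - o, b, i])
                o2 = int(nori[1 - o, b, i])
                start = outdeg[1 - o2, j] != 1
            if start:
                raw.append(walk(i, o))
                break
        else:
            continue

    # anything left is part of an isolated simple cycle
    for i in range(n):
        if not visited[i]:
            raw.append(walk(i, 0))

    out = []
    for seq, cov in raw:
        if len(seq) < min_contig_len:
            continue
        rc = _encode.revcomp_str(seq)
        out.append((min(seq, rc), cov))
    out.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(
            id=f"c{i + 1}_len{len(seq)}_cov{cov:.1f}",
            seq=seq,
            k=k,
            mean_cov=cov,
        )
        for i, (seq, cov) in enumerate(out)
    ]


@dataclass
class Assembly:
    """Ordered contig collection with provenance."""

    contigs: list[Contig]
    k: int
    backend: str = "builtin"
    iteration: Optional[int] = None
    cutoff_used: Optional[int] = None

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_bp(self) -> int:
        return sum(len(c) for c in self.contigs)

    def tag_iteration(self, iteration: int) -> "Assembly":
        """Return a copy whose contig ids carry the iteration prefix."""
        tagged = [
            Contig(
                id=f"it{iteration}_{c.id}",
                seq=c.seq,
                iteration=iteration,
                k=c.k,
                mean_cov=c.mean_cov,
            )
            for c in self.contigs
        ]
        return Assembly(
            contigs=tagged,
            k=self.k,
            backend=self.backend,
            iteration=iteration,
            cutoff_used=self.cutoff_used,
        )


def assemble(reads: Sequence[Read], params: AssemblerParams) -> Assembly:
    """build_graph -> prune -> extract_unitigs with the given parameters."""
    graph = build_graph(reads, params.k)
    cutoff = (
        auto_cutoff(graph) if params.min_kmer_cov == "auto" else int(params.min_kmer_cov)
    )
    pruned = prune(graph, cutoff)
    contigs = extract_unitigs(pruned, params.effective_min_contig_len)
    return Assembly(contigs=contigs, k=params.k, backend="builtin", cutoff_used=cutoff)


# ---------------------------------------------------------------------------
# backend registry: any callable (reads, params) -> Assembly satisfies the
# contract; external assembler adapters are thin templates that shell out.

BackendFn = Callable[[Sequence[Read], AssemblerParams], Assembly]

_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def get_backend(name: str) -> BackendFn:
    if name not in _BACKENDS:
        raise BackendError(
            f"unknown assembler backend {name!r}; registered: "
            + ", ".join(sorted(_BACKENDS))
        )
    return _BACKENDS[name]


def list_backends() -> list[str]:
    return sorted(_BACKENDS)


def _external_backend(executable: str, hint: str) -> BackendFn:
    def run(reads: Sequence[Read], params: AssemblerParams) -> Assembly:
        if shutil.which(executable) is None:
            raise BackendError(
                f"assembler executable {executable!r} not found on PATH; "
                f"install it or use the builtin backend ({hint})"
            )
        raise BackendError(
            f"external backend {executable!r} is a documented command template "
            "and is not executed by this package; register a custom backend "
            "wrapping your preferred invocation"
        )

    return run


register_backend("builtin", assemble)
register_backend(
    "velvet",
    _external_backend("velveth", "velveth/velvetg with -exp_cov auto"),
)
register_backend("abyss", _external_backend("ABYSS", "ABYSS -k<k>"))
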