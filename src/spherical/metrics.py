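"""Assembly-quality statistics.

* N50 — contig length at which the descending running sum first reaches
  half of total assembly bases (>= on both comparisons).
* alignment rate / utilisation — 100 x aligned reads / total input reads.
* false base rate — percentage of assembly positions covered by zero reads
  when the input is mapped back: bases with no read-level evidence.
* contig score — coverage% / 100 x identity% against the best-matching
  reference genome; 100 means the entire contig precisely matches a region
  of the genome it came from, 0 means no matching region at all.

The reference matcher is a deterministic seed-and-extend ungapped
comparator (exact 31-mer anchors, best single maximal segment); it plays
the role a gapped local aligner such as BLASTN would play against known
reference genomes, restricted to ungapped single-segment matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _encode
from .align import CoverageProfile
from .assemble import Assembly
from .io_seq import Contig


@dataclass
class AssemblyStats:
    """Length statistics and read-support rates for one assembly."""

    n_contigs: int
    total_bp: int
    n50: int
    longest: int
    shortest: int
    len_sd: float
    alignment_rate: float
    false_base_rate: float

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_bp": self.total_bp,
            "n50": self.n50,
            "longest": self.longest,
            "shortest": self.shortest,
            "len_sd": round(self.len_sd, 4),
            "alignment_rate": round(self.alignment_rate, 4),
            "false_base_rate": round(self.false_base_rate, 4),
        }


@dataclass
class ReferenceMatch:
    """Best reference placement of one contig."""

    contig_id: str
    genome_id: Optional[str]
    coverage_pct: float
    identity_pct: float

    @property
    def score(self) -> float:
        return contig_score(self.coverage_pct, self.identity_pct)


@dataclass
class MatchParams:
    seed_len: int = 31


def n50(lengths: Sequence[int]) -> int:
    """Smallest length whose descending running sum covers half the total."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for x in ordered:
        running += x
        if running >= half:
            return x
    raise AssertionError("unreachable")


def alignment_rate(n_aligned: int, n_total: int) -> float:
    """Utilisation percentage: 100 x aligned / total input reads."""
    if n_total <= 0:
        raise ValueError("total read count must be positive")
    if not (0 <= n_aligned <= n_total):
        raise ValueError("aligned count outside [0, total]")
    return 100.0 * n_aligned / n_total


def false_base_rate(coverage: CoverageProfile) -> float:
    """Percentage of assembly positions with zero read coverage."""
    total = coverage.total_bp()
    if total == 0:
        raise ValueError("false base rate of an empty assembly is undefined")
    return 100.0 * coverage.zero_positions() / total


def contig_score(coverage_pct: float, identity_pct: float) -> float:
    """coverage% / 100 x identity%, the 0--100 reconstruction score."""
    if not (0 <= coverage_pct <= 100 and 0 <= identity_pct <= 100):
        raise ValueError("coverage_pct and identity_pct must be in [0, 100]")
    return coverage_pct / 100.0 * identity_pct


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment under +1 match / -1 mismatch.

    Returns (start, stop, n_identical); the leftmost optimum on ties.
    Kadane's algorithm over the +/-1 profile keeps the matched region a
    single ungapped segment and trims poorly matching flanks.
    """
    scores = np.where(match, 1, -1)
    best_sum = -1
    best = (0, 0)
    cur_sum = 0
    cur_start = 0
    for i, v in enumerate(scores):
        if cur_sum <= 0:
            cur_sum = 0
            cur_start = i
        cur_sum += int(v)
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    a, b = best
    if best_sum <= 0:
        return 0, 0, 0
    ident = int(np.count_nonzero(match[a:b]))
    return a, b, ident


class _GenomeIndex:
    """Exact canonical seed lookup across a set of reference genomes."""

    def __init__(self, genomes: Sequence[tuple[str, str]], seed_len: int):
        self.seed_len = seed_len
        self.genomes = list(genomes)
        self.codes = [_encode.encode_seq(seq) for _, seq in genomes]
        postings: dict[int, list[tuple[int, int, int]]] = {}
        for gi, codes in enumerate(self.codes):
            if len(codes) < seed_len:
                continue
            mat = codes[None, :]
            lengths = np.array([len(codes)])
            canon, valid = _encode.canonical_kmer_matrix(mat, lengths, seed_len)
            fwd, _ = _encode.forward_kmer_matrix(mat, lengths, seed_len)
            for p in np.nonzero(valid[0])[0].tolist():
                code = int(canon[0, p])
                orient = 0 if int(fwd[0, p]) == code else 1
                postings.setdefault(code, []).append((gi, p, orient))
        self.keys = np.array(sorted(postings), dtype=np.uint64)
        self.postings = [postings[int(kk)] for kk in self.keys]

    def lookup(self, code: int) -> list[tuple[int, int, int]]:
        i = int(np.searchsorted(self.keys, np.uint64(code)))
        if i < len(self.keys) and int(self.keys[i]) == code:
            return self.postings[i]
        return []


def best_reference_match(
    contig: Contig,
    genomes: Sequence[tuple[str, str]],
    match_params: Optional[MatchParams] = None,
    _index: Optional[_GenomeIndex] = None,
) -> ReferenceMatch:
    """Best ungapped single-segment placement of a contig on any genome.

    Candidate diagonals come from exact seed anchors on both strands; each
    candidate is scored by its best +1/-1 segment and the placement with
    the most identical bases wins. A contig sharing no seed with any genome
    scores 0 (no matching region).
    """
    if not genomes:
        raise ValueError("reference genome set is empty")
    params = match_params or MatchParams()
    index = _index if _index is not None else _GenomeIndex(genomes, params.seed_len)
    s = index.seed_len
    Lc = len(contig.seq)
    cmat = _encode.encode_seq(contig.seq)
    if Lc < s:
        return ReferenceMatch(contig.id, None, 0.0, 0.0)
    mat = cmat[None, :]
    lengths = np.array([Lc])
    canon, valid = _encode.canonical_kmer_matrix(mat, lengths, s)
    fwd, _ = _encode.forward_kmer_matrix(mat, lengths, s)

    # candidate diagonals: (genome_idx, offset_of_contig_start, strand)
    cands: set[tuple[int, int, int]] = set()
    for q in np.nonzero(valid[0])[0].tolist():
        code = int(canon[0, q])
        hits = index.lookup(code)
        if not hits:
            continue
        orient_r = 0 if int(fwd[0, q]) == code else 1
        for gi, p, orient_g in hits:
            if orient_r == orient_g:
                cands.add((gi, p - q, 0))
            else:
                cands.add((gi, p - (Lc - s - q), 1))

    if not cands:
        return ReferenceMatch(contig.id, None, 0.0, 0.0)

    rcmat = _encode.revcomp_matrix(cmat)
    best_key = None
    best_result = None
    for gi, ofs, flag in sorted(cands):
        gcodes = index.codes[gi]
        query = rcmat if flag else cmat
        c0 = max(0, -ofs)
        c1 = min(Lc, len(gcodes) - ofs)
        if c1 - c0 < s:
            continue
        match = query[c0:c1] == gcodes[ofs + c0 : ofs + c1]
        a, b, ident = _best_segment(match)
        if ident == 0:
            continue
        seglen = b - a
        # maximise identical bases; prefer '+' strand, then genome order
        key = (-ident, flag, gi, ofs, a)
        if best_key is None or key < best_key:
            best_key = key
            best_result = (gi, seglen, ident)
    if best_result is None:
        return ReferenceMatch(contig.id, None, 0.0, 0.0)
    gi, seglen, ident = best_result
    coverage_pct = 100.0 * seglen / Lc
    identity_pct = 100.0 * ident / seglen
    return ReferenceMatch(contig.id, index.genomes[gi][0], coverage_pct, identity_pct)


def reference_matches(
    contigs: Sequence[Contig],
    genomes: Sequence[tuple[str, str]],
    match_params: Optional[MatchParams] = None,
) -> list[ReferenceMatch]:
    """Best reference match per contig, sharing one genome index."""
    params = match_params or MatchParams()
    index = _GenomeIndex(genomes, params.seed_len)
    return [
        best_reference_match(c, genomes, params, _index=index) for c in contigs
    ]


def assembly_stats(
    assembly: Assembly,
    n_aligned: int,
    input_total: int,
    coverage: Optional[CoverageProfile] = None,
    sd_mode: str = "population",
) -> AssemblyStats:
    """Aggregate length statistics with utilisation and false-base rates.

    ``n_aligned`` is the (cumulative, for merged assemblies) aligned read
    count; ``len_sd`` is the population standard deviation by default.
    """
    lengths = [len(c) for c in assembly.contigs]
    if lengths:
        ddof = 0 if sd_mode == "population" else 1
        sd = float(np.std(lengths, ddof=ddof)) if len(lengths) > ddof else 0.0
        stats_n50 = n50(lengths)
        longest, shortest = max(lengths), min(lengths)
    else:
        sd = 0.0
        stats_n50 = 0
        longest = shortest = 0
    fbr = 0.0
    if coverage is not None and lengths:
        fbr = false_base_rate(coverage)
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bp=sum(lengths),
        n50=stats_n50,
        longest=longest,
        shortest=shortest,
        len_sd=sd,
        alignment_rate=alignment_rate(n_aligned, input_total),
        false_base_rate=fbr,
    )


def write_reference_report(matches: Sequence[ReferenceMatch], path) -> int:
    """TSV report: contig_id, genome_id, coverage_pct, identity_pct, score."""
    with open(path, "w") as fh:
        fh.write("contig_id\tgenome_id\tcoverage_pct\tidentity_pct\tscore\n")
        for m in matches:
            fh.write(
                f"{m.contig_id}\t{m.genome_id or 'NA'}\t{m.coverage_pct:.4f}\t"
                f"{m.identity_pct:.4f}\t{m.score:.4f}\n"
            )
    return len(matches)
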