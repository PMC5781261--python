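"""Seed-and-verify ungapped read aligner and per-base coverage pileups.

The workflow needs a yes/no utilisation oracle: does a read align
end-to-end to the current contig set with at most a small number of
mismatches? Candidate placements are found by exact seed-kmer lookup on
both strands (canonical seed codes); each candidate is verified by a
full-length ungapped comparison. Among valid placements the fewest-mismatch
hit wins, ties broken by (contig id, position, '+' before '-').

Default thresholds approximate a permissive short-read mapper: 22 bp exact
seeds and an end-to-end mismatch budget of ceil(4% of the read length).
Gapped alignment and quality-aware scoring are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import _encode
from .errors import AlignmentError
from .io_seq import Contig, Read


@dataclass
class AlignParams:
    """Aligner thresholds.

    ``max_mismatches=None`` means per-read ceil(0.04 * read_length).
    """

    seed_len: int = 22
    max_mismatches: Optional[int] = None
    both_strands: bool = True

    def mismatch_budget(self, read_length: int) -> int:
        if self.max_mismatches is not None:
            return self.max_mismatches
        return math.ceil(0.04 * read_length)


@dataclass(slots=True)
class AlignmentHit:
    """Best placement of one read on one contig (0-based, ungapped)."""

    read_id: str
    contig_id: str
    pos: int
    strand: str  # '+' or '-'
    mismatches: int
    read_length: int = 0


class SeedIndex:
    """Exact-match lookup from canonical seed codes to contig positions.

    Each posting records (contig index, offset, orientation) where
    orientation 0 means the contig's forward kmer spells the canonical
    code. Palindromic seeds (possible for even seed lengths) are flagged so
    both placements are generated.
    """

    def __init__(self, contigs: Sequence[Contig], seed_len: int):
        if not contigs:
            raise AlignmentError("cannot index an empty contig set")
        if not (4 <= seed_len <= 31):
            raise ValueError("seed_len must be in [4, 31] (2-bit packed seeds)")
        self.seed_len = seed_len
        self.contigs = list(contigs)
        self.contig_lens = np.array([len(c.seq) for c in contigs])
        self.contig_codes: list[np.ndarray] = []
        self.skipped: list[str] = []
        postings: dict[int, list[tuple[int, int, int]]] = {}
        for ci, contig in enumerate(self.contigs):
            codes = _encode.encode_seq(contig.seq)
            self.contig_codes.append(codes)
            if len(contig.seq) < seed_len:
                self.skipped.append(contig.id)
                continue
            mat = codes[None, :]
            lengths = np.array([len(contig.seq)])
            canon, valid = _encode.canonical_kmer_matrix(mat, lengths, seed_len)
            fwd, _ = _encode.forward_kmer_matrix(mat, lengths, seed_len)
            canon0, fwd0, valid0 = canon[0], fwd[0], valid[0]
            for pos in np.nonzero(valid0)[0].tolist():
                code = int(canon0[pos])
                orient = 0 if int(fwd0[pos]) == code else 1
                postings.setdefault(code, []).append((ci, pos, orient))
        if not postings:
            raise AlignmentError(
                f"no contig is long enough to index at seed_len={seed_len}"
            )
        self.keys = np.array(sorted(postings), dtype=np.uint64)
        self.postings = [postings[int(kk)] for kk in self.keys]
        if seed_len % 2 == 0:
            self.key_is_pal = self.keys == _encode.revcomp_codes(self.keys, seed_len)
        else:
            self.key_is_pal = np.zeros(len(self.keys), dtype=bool)

    def key_index(self, code: int) -> int:
        """Index into keys/postings, or -1 when absent."""
        i = int(np.searchsorted(self.keys, np.uint64(code)))
        if i < len(self.keys) and int(self.keys[i]) == code:
            return i
        return -1

    def lookup(self, code: int) -> list[tuple[int, int, int]]:
        i = self.key_index(code)
        return self.postings[i] if i >= 0 else []


def index_contigs(contigs: Sequence[Contig], seed_len: int) -> SeedIndex:
    """Build the seed index; contigs shorter than the seed are skipped."""
    return SeedIndex(contigs, seed_len)


def _add_candidates(
    cands: set[tuple[int, int, int]],
    index: SeedIndex,
    key_idx: int,
    q: int,
    read_len: int,
    read_orient: int,
    both_strands: bool,
) -> None:
    """Add placements implied by the seed at read offset q hitting key_idx."""
    s = index.seed_len
    pal = bool(index.key_is_pal[key_idx])
    for ci, pos, orient_c in index.postings[key_idx]:
        clen = int(index.contig_lens[ci])
        forward_ok = (read_orient == orient_c) or pal
        reverse_ok = (read_orient != orient_c) or pal
        if forward_ok:
            start = pos - q
            if 0 <= start and start + read_len <= clen:
                cands.add((ci, start, 0))
        if reverse_ok and both_strands:
            start = pos - (read_len - s - q)
            if 0 <= start and start + read_len <= clen:
                cands.add((ci, start, 1))


def _best_hit(
    index: SeedIndex,
    read: Read,
    read_codes: np.ndarray,
    cands: set[tuple[int, int, int]],
    budget: int,
) -> Optional[AlignmentHit]:
    """Verify candidates and pick the fewest-mismatch placement."""
    rc_codes: Optional[np.ndarray] = None
    best = None
    L = len(read_codes)
    for cand in sorted(cands):
        ci, start, flag = cand
        if flag:
            if rc_codes is None:
                rc_codes = _encode.revcomp_matrix(read_codes)
            query = rc_codes
        else:
            query = read_codes
        mm = int(
            np.count_nonzero(index.contig_codes[ci][start : start + L] != query)
        )
        if mm > budget:
            continue
        key = (mm, index.contigs[ci].id, start, flag)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mm, cid, start, flag = best
    return AlignmentHit(
        read_id=read.id,
        contig_id=cid,
        pos=start,
        strand="-" if flag else "+",
        mismatches=mm,
        read_length=L,
    )


def align_read(
    read: Read, index: SeedIndex, params: AlignParams
) -> Optional[AlignmentHit]:
    """Best end-to-end ungapped placement of one read, or None.

    Reads shorter than the seed length cannot be anchored and are reported
    as unaligned.
    """
    L = len(read.seq)
    if L < index.seed_len:
        return None
    s = index.seed_len
    mat, lengths = _encode.encode_matrix([read.seq])
    canon, valid = _encode.canonical_kmer_matrix(mat, lengths, s)
    fwd, _ = _encode.forward_kmer_matrix(mat, lengths, s)
    cands: set[tuple[int, int, int]] = set()
    for q in np.nonzero(valid[0])[0].tolist():
        code = int(canon[0, q])
        ki = index.key_index(code)
        if ki < 0:
            continue
        read_orient = 0 if int(fwd[0, q]) == code else 1
        _add_candidates(cands, index, ki, q, L, read_orient, params.both_strands)
    if not cands:
        return None
    return _best_hit(index, read, mat[0, :L], cands, params.mismatch_budget(L))


def partition_reads(
    reads: Sequence[Read],
    contigs: Sequence[Contig],
    params: AlignParams,
) -> tuple[list[AlignmentHit], list[Read]]:
    """Split reads into (aligned hits, unaligned reads). Exhaustive and
    exclusive: every read lands in exactly one bucket.

    Vectorised bulk path: all seed codes of all reads are matched against
    the index keys in one searchsorted pass; only reads with at least one
    seed hit enter the per-read verification loop.
    """
    if not contigs:
        return [], list(reads)
    try:
        index = SeedIndex(contigs, params.seed_len)
    except AlignmentError:
        return [], list(reads)

    s = index.seed_len
    seqs = [r.seq for r in reads]
    if not seqs:
        return [], []
    mat, lengths = _encode.encode_matrix(seqs)
    canon, valid = _encode.canonical_kmer_matrix(mat, lengths, s)
    fwd, _ = _encode.forward_kmer_matrix(mat, lengths, s)

    if canon.size:
        pos = np.searchsorted(index.keys, canon)
        pos_c = np.minimum(pos, len(index.keys) - 1)
        seed_hit = valid & (pos < len(index.keys)) & (index.keys[pos_c] == canon)
    else:
        pos_c = np.zeros_like(canon, dtype=np.int64)
        seed_hit = np.zeros_like(valid)

    hits: list[AlignmentHit] = []
    unaligned: list[Read] = []
    any_hit = seed_hit.any(axis=1) if seed_hit.size else np.zeros(len(reads), bool)
    for i, read in enumerate(reads):
        L = int(lengths[i])
        if L < s or not any_hit[i]:
            unaligned.append(read)
            continue
        cands: set[tuple[int, int, int]] = set()
        row_canon, row_fwd = canon[i], fwd[i]
        for q in np.nonzero(seed_hit[i])[0].tolist():
            code = int(row_canon[q])
            read_orient = 0 if int(row_fwd[q]) == code else 1
            _add_candidates(
                cands, index, int(pos_c[i, q]), q, L, read_orient, params.both_strands
            )
        hit = (
            _best_hit(index, read, mat[i, :L], cands, params.mismatch_budget(L))
            if cands
            else None
        )
        if hit is None:
            unaligned.append(read)
        else:
            hits.append(hit)
    assert len(hits) + len(unaligned) == len(reads)
    return hits, unaligned


class CoverageProfile:
    """Per-contig integer pileups, one entry per contig base."""

    def __init__(self, contigs: Sequence[Contig]):
        self.vectors: dict[str, np.ndarray] = {
            c.id: np.zeros(len(c.seq), dtype=np.int64) for c in contigs
        }

    def total_mass(self) -> int:
        return int(sum(v.sum() for v in self.vectors.values()))

    def total_bp(self) -> int:
        return int(sum(len(v) for v in self.vectors.values()))

    def zero_positions(self) -> int:
        return int(sum(np.count_nonzero(v == 0) for v in self.vectors.values()))


def coverage_profile(
    contigs: Sequence[Contig],
    hits: Sequence[AlignmentHit],
    read_length: Union[int, Mapping[str, int], None] = None,
) -> CoverageProfile:
    """Pileup of hit footprints; strand-independent.

    ``read_length`` may be a scalar, a read_id -> length map, or None to
    use the length recorded on each hit.
    """
    profile = CoverageProfile(contigs)
    for hit in hits:
        if isinstance(read_length, int):
            L = read_length
        elif read_length is not None:
            L = read_length[hit.read_id]
        else:
            L = hit.read_length
        if L <= 0:
            raise ValueError(f"hit {hit.read_id}: unknown read length")
        vec = profile.vectors.get(hit.contig_id)
        if vec is None:
            raise AlignmentError(f"hit references unknown contig {hit.contig_id!r}")
        if hit.pos < 0 or hit.pos + L > len(vec):
            raise AlignmentError(
                f"hit {hit.read_id} out of bounds on contig {hit.contig_id}"
            )
        vec[hit.pos : hit.pos + L] += 1
    return profile


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> int:
    """Optional alignment dump: read_id, contig_id, pos(0-based), strand,
    mismatches."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\tpos\tstrand\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.contig_id}\t{h.pos}\t{h.strand}\t{h.mismatches}\n"
            )
    return len(hits)
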