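"""A deterministic seed-and-extend short-read aligner implementing the
fraction-based acceptance contract used for every mapping step in the
pipeline (direct, sequential, and combined).

A placement is admissible iff

    length fraction     = aligned read bases / read length      >= min_length_fraction
    similarity fraction = matches / alignment columns           >= min_similarity_fraction

Extension is a banded local alignment (match +1, mismatch -2, gap -3,
linear gaps) around clustered exact k-mer seeds; read bases outside the
locally optimal alignment are soft-clipped and count against the length
fraction. Ties between equal-score placements are broken lexicographically
by (contig, start, strand) so results are fully deterministic.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .reference_io import (
    CombinedReference,
    Contig,
    Genome,
    SequencedRead,
    UsageError,
    reverse_complement,
)

logger = logging.getLogger("dualmap.mapper")

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_SCORE = -3

# Admissibility fractions are compared with this slack so that exact
# boundary cases (e.g. 16 matches / 20 columns at threshold 0.8) are not
# lost to floating-point rounding.
_EPS = 1e-9


@dataclass(frozen=True)
class MappingParams:
    """Mapping acceptance contract and seeding knobs.

    The default 0.8/0.8 regime is the standard eukaryote mapping setup; the
    stricter bacterial regime raises min_length_fraction to 0.9.
    """

    min_length_fraction: float = 0.8
    min_similarity_fraction: float = 0.8
    max_hits_reported: int = 10
    kmer_size: int = 15
    max_seed_extensions: int = 50
    paired: bool = False
    insert_range: tuple[int, int] = (100, 500)

    def __post_init__(self) -> None:
        for name in ("min_length_fraction", "min_similarity_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise UsageError(f"{name} must be in (0, 1], got {v}")
        if self.max_hits_reported < 1:
            raise UsageError("max_hits_reported must be positive")
        if self.kmer_size < 1:
            raise UsageError("kmer_size must be positive")


@dataclass(frozen=True)
class Placement:
    """One admissible alignment of a read on the reference.

    ``start``/``end`` are 0-based half-open reference coordinates. For a
    '-' strand placement the CIGAR and clip counts refer to the
    reverse-complemented read (reference-forward orientation, as in SAM).
    """

    contig: str
    start: int
    end: int
    strand: str
    aligned_read_bases: int
    matches: int
    aligned_columns: int
    score: int
    length_fraction: float
    similarity_fraction: float
    cigar: str = ""
    clip_left: int = 0
    clip_right: int = 0


@dataclass
class MappingResult:
    """All admissible placements of one read, best-score first."""

    read_id: str
    placements: list[Placement]
    status: str  # unique | multi | unmapped
    broken_pair: bool = False

    @property
    def best(self) -> Placement | None:
        return self.placements[0] if self.placements else None


class KmerIndex:
    """Exact k-mer -> (contig, position, strand) lookup over both strands.

    A '-' entry at (contig, p) means the reverse complement of the indexed
    k-mer occurs at position p of the forward contig sequence.
    """

    def __init__(self, reference: Genome | CombinedReference, k: int):
        if k < 8:
            raise UsageError(f"k-mer size {k} is too unspecific (minimum 8)")
        self.k = k
        if isinstance(reference, CombinedReference):
            self.provenance: dict[str, str] = dict(reference.provenance)
        else:
            self.provenance = {c.name: reference.organism_id for c in reference.contigs}
        self.contig_seqs: dict[str, str] = {c.name: c.sequence for c in reference.contigs}
        self.contig_arrays: dict[str, np.ndarray] = {
            c.name: np.frombuffer(c.sequence.encode("ascii"), dtype=np.uint8)
            for c in reference.contigs
        }
        index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for name, seq in self.contig_seqs.items():
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if "N" in km:
                    continue
                index[km].append((name, i, "+"))
                index[reverse_complement(km)].append((name, i, "-"))
        self.index: dict[str, list[tuple[str, int, str]]] = dict(index)

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.index.get(kmer, [])

    def contig_length(self, name: str) -> int:
        return len(self.contig_seqs[name])


def build_index(reference: Genome | CombinedReference, k: int = 15) -> KmerIndex:
    """Build the exact k-mer index of a reference (both strands)."""
    return KmerIndex(reference, k)


# ---------------------------------------------------------------------------
# Local alignment (extension)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Alignment:
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    matches: int
    columns: int
    cigar: str


def _local_align(query: np.ndarray, window: np.ndarray) -> _Alignment | None:
    """Best local alignment of query vs window (linear gaps).

    The DP is computed row-by-row over the query with the horizontal-gap
    recurrence folded into a running maximum (valid for linear gap costs),
    so each row is a handful of vectorized operations over the window.
    """
    n, m = int(query.size), int(window.size)
    if n == 0 or m == 0:
        return None
    pen = -GAP_SCORE
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    idx = np.arange(1, m + 1, dtype=np.int32) * pen
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(window == query[i - 1], MATCH_SCORE, MISMATCH_SCORE).astype(np.int32)
        tmp = np.maximum(prev[:-1] + sub, prev[1:] + GAP_SCORE)
        np.maximum(tmp, 0, out=tmp)
        # H[i, j] = max(tmp_j, H[i, j-1] - pen): a running max over tmp + pen*j
        tmp += idx
        np.maximum.accumulate(tmp, out=tmp)
        H[i, 1:] = tmp - idx
    flat = int(H.argmax())
    bi, bj = divmod(flat, m + 1)
    score = int(H[bi, bj])
    if score <= 0:
        return None
    # traceback (preference: diagonal, then vertical, then horizontal)
    i, j = bi, bj
    matches = 0
    ops: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH_SCORE if window[j - 1] == query[i - 1] else MISMATCH_SCORE
        if H[i, j] == H[i - 1, j - 1] + s:
            ops.append("M")
            matches += s == MATCH_SCORE
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP_SCORE:
            ops.append("I")
            i -= 1
        elif H[i, j] == H[i, j - 1] + GAP_SCORE:
            ops.append("D")
            j -= 1
        else:  # pragma: no cover - recurrence guarantees a predecessor
            break
    ops.reverse()
    cigar_parts: list[str] = []
    for op in ops:
        if cigar_parts and cigar_parts[-1][-1] == op:
            run, _ = cigar_parts[-1][:-1], op
            cigar_parts[-1] = f"{int(run) + 1}{op}"
        else:
            cigar_parts.append(f"1{op}")
    return _Alignment(
        score=score,
        read_start=i,
        read_end=bi,
        ref_start=j,
        ref_end=bj,
        matches=matches,
        columns=len(ops),
        cigar="".join(cigar_parts),
    )


def band_width(read_length: int, params: MappingParams) -> int:
    return math.ceil(read_length * (1.0 - params.min_similarity_fraction)) + 2


def _admissible(aln: _Alignment, read_length: int, params: MappingParams) -> bool:
    lf = (aln.read_end - aln.read_start) / read_length
    sf = aln.matches / aln.columns if aln.columns else 0.0
    return (
        lf + _EPS >= params.min_length_fraction
        and sf + _EPS >= params.min_similarity_fraction
    )


def _placement_from(
    aln: _Alignment, contig: str, window_offset: int, strand: str, read_length: int
) -> Placement:
    aligned = aln.read_end - aln.read_start
    return Placement(
        contig=contig,
        start=window_offset + aln.ref_start,
        end=window_offset + aln.ref_end,
        strand=strand,
        aligned_read_bases=aligned,
        matches=aln.matches,
        aligned_columns=aln.columns,
        score=aln.score,
        length_fraction=aligned / read_length,
        similarity_fraction=aln.matches / aln.columns,
        cigar=aln.cigar,
        clip_left=aln.read_start,
        clip_right=read_length - aln.read_end,
    )


def align_extend(
    read: str | SequencedRead,
    contig: Contig,
    seed_position: int,
    strand: str,
    params: MappingParams = MappingParams(),
) -> Placement | None:
    """Extend a single seed: banded local alignment of the read around the
    projected reference start ``seed_position`` on ``contig``.

    Returns the placement iff it satisfies both acceptance fractions,
    otherwise None. For strand '-' the reverse complement of the read is
    aligned against the forward contig sequence.
    """
    seq = read.sequence if isinstance(read, SequencedRead) else read
    if not (0 <= seed_position < len(contig)):
        raise UsageError(f"seed position {seed_position} outside contig {contig.name!r}")
    n = len(seq)
    band = band_width(n, params)
    w0 = max(0, seed_position - band)
    w1 = min(len(contig), seed_position + n + band)
    query = seq if strand == "+" else reverse_complement(seq)
    qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    warr = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)[w0:w1]
    aln = _local_align(qarr, warr)
    if aln is None or not _admissible(aln, n, params):
        return None
    return _placement_from(aln, contig.name, w0, strand, n)


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

def _seed_clusters(
    seq: str, index: KmerIndex, band: int
) -> list[tuple[str, str, int, int, int]]:
    """Collect seed hits and cluster them by (contig, strand) diagonal.

    Returns (contig, strand, diag_min, diag_max, n_seeds) tuples. The
    diagonal of a hit is the projected 0-based reference start of the read.
    """
    k = index.k
    n = len(seq)
    diagonals: dict[tuple[str, str], list[int]] = defaultdict(list)
    for offset in range(n - k + 1):
        for contig, pos, strand in index.lookup(seq[offset : offset + k]):
            if strand == "+":
                diag = pos - offset
            else:
                # the read k-mer matches the '-' strand: the reverse
                # complement of the read aligns forward, where this k-mer
                # sits at offset n - k - offset
                diag = pos - (n - k - offset)
            diagonals[(contig, strand)].append(diag)
    clusters: list[tuple[str, str, int, int, int]] = []
    for (contig, strand), diags in diagonals.items():
        diags.sort()
        lo = hi = diags[0]
        count = 1
        for d in diags[1:]:
            if d - hi > band:
                clusters.append((contig, strand, lo, hi, count))
                lo = hi = d
                count = 1
            else:
                hi = d
                count += 1
        clusters.append((contig, strand, lo, hi, count))
    return clusters


def map_read(
    read: str | SequencedRead, index: KmerIndex, params: MappingParams = MappingParams()
) -> MappingResult:
    """Map one read: seed, cluster, extend, filter by the acceptance
    fractions, deduplicate by (contig, start, strand), and rank.

    Placements are sorted by score (descending) then (contig, start,
    strand); at most ``params.max_hits_reported`` are kept. Status is
    ``unique`` for exactly one admissible placement, ``multi`` for two or
    more, ``unmapped`` for none.
    """
    if isinstance(read, SequencedRead):
        read_id, seq = read.name, read.sequence
    else:
        read_id, seq = "read", read
    n = len(seq)
    if n < index.k:
        logger.warning("read %s is shorter (%d) than k=%d; unmapped", read_id, n, index.k)
        return MappingResult(read_id, [], "unmapped")
    band = band_width(n, params)
    clusters = _seed_clusters(seq, index, band)
    # Most-seeded clusters first; deterministic tie-break; cap extensions.
    clusters.sort(key=lambda c: (-c[4], c[0], c[2], c[1]))
    clusters = clusters[: params.max_seed_extensions]

    rc = reverse_complement(seq)
    qarrs = {
        "+": np.frombuffer(seq.encode("ascii"), dtype=np.uint8),
        "-": np.frombuffer(rc.encode("ascii"), dtype=np.uint8),
    }
    best: dict[tuple[str, int, str], Placement] = {}
    for contig, strand, dlo, dhi, _count in clusters:
        clen = index.contig_length(contig)
        w0 = max(0, dlo - band)
        w1 = min(clen, dhi + n + band)
        if w1 <= w0:
            continue
        aln = _local_align(qarrs[strand], index.contig_arrays[contig][w0:w1])
        if aln is None or not _admissible(aln, n, params):
            continue
        p = _placement_from(aln, contig, w0, strand, n)
        key = (p.contig, p.start, p.strand)
        if key not in best or p.score > best[key].score:
            best[key] = p
    ranked = sorted(best.values(), key=lambda p: (-p.score, p.contig, p.start, p.strand))
    # One placement per locus: a weaker alignment overlapping a stronger
    # one on the same contig and strand is a truncated or shifted view of
    # the same locus (e.g. from a window cut by a stray seed), not an
    # independent hit.
    placements: list[Placement] = []
    for p in ranked:
        if any(
            q.contig == p.contig
            and q.strand == p.strand
            and p.start < q.end
            and q.start < p.end
            for q in placements
        ):
            continue
        placements.append(p)
        if len(placements) == params.max_hits_reported:
            break
    if not placements:
        status = "unmapped"
    elif len(placements) == 1:
        status = "unique"
    else:
        status = "multi"
    return MappingResult(read_id, placements, status)


def _is_proper(p1: Placement, p2: Placement, insert_range: tuple[int, int]) -> bool:
    if p1.contig != p2.contig or p1.strand == p2.strand:
        return False
    insert = max(p1.end, p2.end) - min(p1.start, p2.start)
    return insert_range[0] <= insert <= insert_range[1]


def map_pair(
    read1: str | SequencedRead,
    read2: str | SequencedRead,
    index: KmerIndex,
    params: MappingParams = MappingParams(),
) -> tuple[MappingResult, MappingResult]:
    """Map a read pair. If some placement pair lies on one contig, on
    opposite strands, within the insert range, both results are returned as
    a proper pair; otherwise each mate is kept independently with
    ``broken_pair=True`` (broken pairs are retained downstream)."""
    r1 = map_read(read1, index, params)
    r2 = map_read(read2, index, params)
    proper = any(
        _is_proper(p1, p2, params.insert_range)
        for p1 in r1.placements
        for p2 in r2.placements
    )
    if not proper:
        r1.broken_pair = True
        r2.broken_pair = True
    return r1, r2


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------

def write_sam(
    results: Iterable[tuple[SequencedRead, MappingResult]],
    index: KmerIndex,
    path: str,
) -> None:
    """Write mapping results as plain-text SAM.

    Emits the mandatory fields plus NH (number of admissible hits) and XO
    (organism of the placement's contig, from reference provenance).
    Secondary placements carry flag 0x100.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in index.contig_seqs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:dualmap\tPN:dualmap\n")
        for read, result in results:
            qname = read.name.split()[0]
            if not result.placements:
                fh.write(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t{read.quality}\n")
                continue
            nh = len(result.placements)
            for rank, p in enumerate(result.placements):
                flag = (16 if p.strand == "-" else 0) | (256 if rank > 0 else 0)
                if p.strand == "-":
                    seq = reverse_complement(read.sequence)
                    qual = read.quality[::-1]
                else:
                    seq, qual = read.sequence, read.quality
                cigar = p.cigar
                if p.clip_left:
                    cigar = f"{p.clip_left}S{cigar}"
                if p.clip_right:
                    cigar = f"{cigar}{p.clip_right}S"
                org = index.provenance.get(p.contig, "*")
                fh.write(
                    f"{qname}\t{flag}\t{p.contig}\t{p.start + 1}\t255\t{cigar}\t*\t0\t0\t"
                    f"{seq}\t{qual}\tNH:i:{nh}\tXO:Z:{org}\tAS:i:{p.score}\n"
                )
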