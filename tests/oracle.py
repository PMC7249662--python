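"""Independent brute-force alignment oracles used only by the tests.

Two layers, deliberately separate from the package's aligner:

* ``plain_local_align`` — a textbook Smith-Waterman with linear gaps in
  pure Python (no banding, no vectorization tricks). This is the ground
  truth for alignment scores and tracebacks on small instances.
* ``oracle_placements`` — the full admissible-placement set of a read on a
  genome, found by exhaustive full-matrix dynamic programming over every
  contig and strand with iterative masking of found placements (so
  repeated loci are all recovered). Uses the same scoring and the same
  best-cell / traceback tie rules as the package so placement sets are
  comparable, but none of the package's seeding, clustering or banding.

The numpy full-matrix scan is itself cross-checked against
``plain_local_align`` in the test suite.
"""

from __future__ import annotations

import numpy as np

from dualmap.mapper import GAP_SCORE, MATCH_SCORE, MISMATCH_SCORE, MappingParams
from dualmap.reference_io import Genome, reverse_complement

_EPS = 1e-9


def plain_local_align(query: str, window: str):
    """Textbook local alignment. Returns (score, q0, q1, w0, w1, matches,
    columns) of the best local alignment, or None if no positive score.
    Best cell: first maximum in row-major order; traceback preference
    diagonal, vertical (query gap consumes query base), horizontal."""
    n, m = len(query), len(window)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = MATCH_SCORE if window[j - 1] == qc else MISMATCH_SCORE
            v = prev[j - 1] + s
            u = prev[j] + GAP_SCORE
            if u > v:
                v = u
            left = row[j - 1] + GAP_SCORE
            if left > v:
                v = left
            if v < 0:
                v = 0
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return None
    i, j, matches, columns = bi, bj, 0, 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = MATCH_SCORE if window[j - 1] == query[i - 1] else MISMATCH_SCORE
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += s == MATCH_SCORE
            columns += 1
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + GAP_SCORE:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, i, bi, j, bj, matches, columns


def _numpy_best_local(query: np.ndarray, ref: np.ndarray):
    """Best local alignment over a whole reference, full matrix (no band).

    Row-wise DP: vertical/diagonal candidates first, then the horizontal
    linear-gap closure as a running maximum. Returns the same tuple shape
    as plain_local_align.
    """
    n, m = query.size, ref.size
    pen = -GAP_SCORE
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    shift = np.arange(1, m + 1, dtype=np.int32) * pen
    for i in range(1, n + 1):
        prev = H[i - 1]
        cand = np.where(ref == query[i - 1], MATCH_SCORE, MISMATCH_SCORE).astype(np.int32)
        cand += prev[:-1]
        np.maximum(cand, prev[1:] + GAP_SCORE, out=cand)
        np.maximum(cand, 0, out=cand)
        cand += shift
        np.maximum.accumulate(cand, out=cand)
        H[i, 1:] = cand - shift
    bi, bj = divmod(int(H.argmax()), m + 1)
    best = int(H[bi, bj])
    if best <= 0:
        return None
    i, j, matches, columns = bi, bj, 0, 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH_SCORE if ref[j - 1] == query[i - 1] else MISMATCH_SCORE
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += s == MATCH_SCORE
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP_SCORE:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, i, bi, j, bj, matches, columns


def oracle_placements(
    read: str, genome: Genome, params: MappingParams, max_rounds: int = 30
) -> set[tuple[str, int, str, int]]:
    """All admissible placements of ``read`` on ``genome`` as a set of
    (contig, start, strand, score), by exhaustive DP with masking."""
    n = len(read)
    out: set[tuple[str, int, str, int]] = set()
    # any admissible placement scores at least ~0.16 * aligned bases; stop
    # scanning below a conservative floor
    floor = max(1, int(0.1 * n))
    for contig in genome.contigs:
        for strand in ("+", "-"):
            query = read if strand == "+" else reverse_complement(read)
            qarr = np.frombuffer(query.encode(), dtype=np.uint8)
            ref = np.frombuffer(contig.sequence.encode(), dtype=np.uint8).copy()
            for _ in range(max_rounds):
                aln = _numpy_best_local(qarr, ref)
                if aln is None or aln[0] < floor:
                    break
                score, q0, q1, w0, w1, matches, columns = aln
                lf = (q1 - q0) / n
                sf = matches / columns if columns else 0.0
                if (
                    lf + _EPS >= params.min_length_fraction
                    and sf + _EPS >= params.min_similarity_fraction
                ):
                    out.add((contig.name, w0, strand, score))
                ref[w0:w1] = 0  # mask the found locus, keep scanning
    return out
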