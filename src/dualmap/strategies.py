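"""The three read-partitioning strategies for dual RNA-seq libraries:
sequential with either genome first, and combined (concatenated reference),
plus read extraction and the closed-form sequential accounting.

Sequential partitioning deliberately ignores relative alignment scores —
the first genome that yields any admissible placement wins. That bias is
the phenomenon the evaluation module measures, so it must not be
"improved" here. The combined strategy attributes each read to the
organism of its best-scoring placement and removes score ties as
ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .mapper import KmerIndex, MappingParams, build_index, map_read
from .reference_io import (
    CombinedReference,
    ConsistencyError,
    Genome,
    SequencedRead,
    UsageError,
    write_fastq,
)
from .simulate import parse_truth_tag

logger = logging.getLogger("dualmap.strategies")

UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Attribution:
    """Per-read organism assignment under one strategy.

    ``detail`` records how the assignment arose: first_pass / second_pass
    for sequential, mapped / ambiguous / no_hit for combined. Ambiguous
    reads (equal best scores on both organisms) and no-hit reads are both
    assigned ``unmapped`` but stay distinguishable here.
    """

    read_id: str
    assigned: str
    truth: str | None
    strategy: str
    detail: str = ""


@dataclass
class AttributionTable:
    """All attributions of one run; every input read appears exactly once."""

    rows: list[Attribution]
    strategy: str

    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in self.rows:
            out[row.assigned] = out.get(row.assigned, 0) + 1
        return out

    def false_attributions(self) -> int:
        """Reads assigned to an organism other than their true origin
        (unmapped/removed reads do not count as false)."""
        return sum(
            1
            for r in self.rows
            if r.truth is not None and r.assigned != UNMAPPED and r.assigned != r.truth
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [r.read_id for r in self.rows],
                "assigned": [r.assigned for r in self.rows],
                "truth": [r.truth if r.truth is not None else "unknown" for r in self.rows],
                "strategy": [r.strategy for r in self.rows],
                "detail": [r.detail for r in self.rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


TruthFn = Callable[[str], str | None]


def _default_truth(read_name: str) -> str | None:
    tag = parse_truth_tag(read_name)
    return tag.origin if tag else None


def sequential_partition(
    reads: Iterable[SequencedRead],
    first: Genome,
    second: Genome,
    params: MappingParams = MappingParams(),
    *,
    first_index: KmerIndex | None = None,
    second_index: KmerIndex | None = None,
    truth_fn: TruthFn = _default_truth,
) -> AttributionTable:
    """Sequential partitioning: map every read to ``first``; any read with
    an admissible placement is attributed to it regardless of score. Only
    the remainder is mapped to ``second``. Both genome orders are this one
    operation with the arguments swapped."""
    if first.organism_id == second.organism_id:
        raise UsageError("sequential partition needs two distinct organisms")
    idx1 = first_index or build_index(first, params.kmer_size)
    idx2 = second_index or build_index(second, params.kmer_size)
    strategy = f"sequential_{first.organism_id}_first"
    rows: list[Attribution] = []
    n_first = n_second = n_unmapped = 0
    for read in reads:
        truth = truth_fn(read.name)
        if map_read(read, idx1, params).placements:
            rows.append(Attribution(read.name, first.organism_id, truth, strategy, "first_pass"))
            n_first += 1
        elif map_read(read, idx2, params).placements:
            rows.append(Attribution(read.name, second.organism_id, truth, strategy, "second_pass"))
            n_second += 1
        else:
            rows.append(Attribution(read.name, UNMAPPED, truth, strategy, "no_hit"))
            n_unmapped += 1
    logger.info(
        "sequential (%s first): %d -> %s, %d -> %s, %d unmapped",
        first.organism_id, n_first, first.organism_id, n_second,
        second.organism_id, n_unmapped,
    )
    return AttributionTable(rows, strategy)


def combined_partition(
    reads: Iterable[SequencedRead],
    combined: CombinedReference,
    params: MappingParams = MappingParams(),
    tie_margin: float = 0.0,
    *,
    index: KmerIndex | None = None,
    truth_fn: TruthFn = _default_truth,
) -> AttributionTable:
    """Combined partitioning: map each read once against the concatenated
    reference and attribute it to the organism holding the better
    best-score placement. Reads whose best scores on the two organisms
    differ by at most ``tie_margin`` align equally well to both genomes and
    are removed (assigned unmapped, detail ``ambiguous``)."""
    if tie_margin < 0:
        raise UsageError("tie_margin must be >= 0")
    idx = index or build_index(combined, params.kmer_size)
    org_a, org_b = combined.organisms
    strategy = "combined"
    rows: list[Attribution] = []
    counts = {org_a: 0, org_b: 0, "ambiguous": 0, "no_hit": 0}
    for read in reads:
        truth = truth_fn(read.name)
        result = map_read(read, idx, params)
        best: dict[str, int] = {}
        for p in result.placements:
            org = combined.provenance[p.contig]
            if org not in best or p.score > best[org]:
                best[org] = p.score
        if not best:
            rows.append(Attribution(read.name, UNMAPPED, truth, strategy, "no_hit"))
            counts["no_hit"] += 1
        elif len(best) == 2 and abs(best[org_a] - best[org_b]) <= tie_margin:
            rows.append(Attribution(read.name, UNMAPPED, truth, strategy, "ambiguous"))
            counts["ambiguous"] += 1
        else:
            winner = max(best, key=lambda org: best[org])
            rows.append(Attribution(read.name, winner, truth, strategy, "mapped"))
            counts[winner] += 1
    logger.info(
        "combined: %d -> %s, %d -> %s, %d ambiguous, %d no hit",
        counts[org_a], org_a, counts[org_b], org_b,
        counts["ambiguous"], counts["no_hit"],
    )
    return AttributionTable(rows, strategy)


def extract_reads(
    table: AttributionTable,
    reads: Iterable[SequencedRead],
    organism: str,
    out: str | Path,
) -> int:
    """Write exactly the reads assigned to ``organism`` (input order
    preserved) to a FASTQ file; returns the number written. ``organism``
    may be ``unmapped`` to extract the removed reads for inspection."""
    assigned = {r.read_id: r.assigned for r in table.rows}
    selected: list[SequencedRead] = []
    for read in reads:
        if read.name not in assigned:
            raise ConsistencyError(f"read {read.name!r} absent from attribution table")
        if assigned[read.name] == organism:
            selected.append(read)
    return write_fastq(selected, out)


def sequential_attribution_counts(
    n_a: int,
    n_b: int,
    cross_a_to_b: int,
    cross_b_to_a: int,
    order: str,
    organisms: tuple[str, str] = ("A", "B"),
) -> dict[str, int]:
    """Closed-form sequential attribution for a chimera library in which
    every read maps to its own genome (true of a chimera built from
    direct-mapping-filtered libraries).

    ``n_a``/``n_b`` are the library sizes; ``cross_a_to_b`` the number of A
    reads also admissible on B's genome, and vice versa. With A first, A
    receives its whole library plus B's cross-mappers; B keeps the rest.
    """
    if not (0 <= cross_a_to_b <= n_a and 0 <= cross_b_to_a <= n_b):
        raise UsageError("cross-mapping counts must be within the library sizes")
    org_a, org_b = organisms
    if order == "A_first":
        return {org_a: n_a + cross_b_to_a, org_b: n_b - cross_b_to_a, UNMAPPED: 0}
    if order == "B_first":
        return {org_a: n_a - cross_a_to_b, org_b: n_b + cross_a_to_b, UNMAPPED: 0}
    raise UsageError(f"order must be 'A_first' or 'B_first', got {order!r}")
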