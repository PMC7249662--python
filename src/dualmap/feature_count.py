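"""Feature-level read counting for a partitioned library against its own
organism's annotation, in the categories reported by dual RNA-seq
count tables: tRNA, rRNA, CDS-unique, CDS-multi, unmapped, and the
multi-read proportion.

A read is excluded (tallied unmapped) if it has more admissible placements
than ``max_hits`` or if none of its placements overlaps an annotated
feature (intergenic exclusion). Otherwise it is counted exactly once at
one feature: the best-scoring feature-overlapping placement decides the
locus; within that placement, the feature with the largest overlap wins,
ties broken by category priority rRNA > tRNA > CDS, then lowest start.
Multi-placed reads are tallied as "multi" (CDS only is split in the
summary; tRNA/rRNA aggregate unique and multi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .mapper import KmerIndex, MappingParams, build_index, map_read
from .reference_io import ConsistencyError, Feature, Genome, SequencedRead

logger = logging.getLogger("dualmap.feature_count")

_CATEGORY_PRIORITY = {"rRNA": 0, "tRNA": 1, "CDS": 2}


@dataclass(frozen=True)
class CountParams:
    """Counting contract: acceptance fractions as in mapping, a cap on the
    number of admissible placements, and intergenic exclusion."""

    max_hits: int = 5
    exclude_intergenic: bool = True
    min_length_fraction: float = 0.8
    min_similarity_fraction: float = 0.8
    kmer_size: int = 15

    def mapping_params(self) -> MappingParams:
        # report one hit beyond the cap so "more than max_hits" is detectable
        return MappingParams(
            min_length_fraction=self.min_length_fraction,
            min_similarity_fraction=self.min_similarity_fraction,
            max_hits_reported=self.max_hits + 1,
            kmer_size=self.kmer_size,
        )


@dataclass
class CountSummary:
    """Reads per category for one library/genome, plus a per-feature table
    (feature_id -> unique, multi) suitable for downstream expression tools.

    ``intergenic`` is only populated when intergenic exclusion is turned
    off; with the default contract such reads are tallied as unmapped.
    Conservation: trna + rrna + cds_unique + cds_multi + unmapped +
    intergenic == total_reads.
    """

    trna: int = 0
    rrna: int = 0
    cds_unique: int = 0
    cds_multi: int = 0
    unmapped: int = 0
    intergenic: int = 0
    total_reads: int = 0
    per_feature: dict[str, list[int]] = field(default_factory=dict)

    @property
    def counted(self) -> int:
        return self.trna + self.rrna + self.cds_unique + self.cds_multi

    def to_row(self) -> dict[str, object]:
        return {
            "tRNA": self.trna,
            "rRNA": self.rrna,
            "CDS_unique": self.cds_unique,
            "CDS_multi": self.cds_multi,
            "unmapped": self.unmapped,
            "multiread_proportion_pct": round(multiread_proportion(self), 2),
        }

    def per_feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.per_feature),
                "unique": [v[0] for v in self.per_feature.values()],
                "multi": [v[1] for v in self.per_feature.values()],
            }
        )


def _build_trees(features: Sequence[Feature], genome: Genome) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    known = set(genome.contig_names)
    for f in features:
        if f.contig not in known:
            raise ConsistencyError(
                f"feature {f.feature_id!r} references unknown contig {f.contig!r}"
            )
        trees.setdefault(f.contig, IntervalTree())[f.start : f.end] = f
    return trees


def count_reads(
    reads: Iterable[SequencedRead],
    genome: Genome,
    features: Sequence[Feature],
    params: CountParams = CountParams(),
    *,
    index: KmerIndex | None = None,
) -> CountSummary:
    """Map each read to the genome and tally it per the counting contract."""
    trees = _build_trees(features, genome)
    idx = index or build_index(genome, params.kmer_size)
    mp = params.mapping_params()
    summary = CountSummary(
        per_feature={f.feature_id: [0, 0] for f in features}
    )
    for read in reads:
        summary.total_reads += 1
        result = map_read(read, idx, mp)
        if not result.placements or len(result.placements) > params.max_hits:
            summary.unmapped += 1
            continue
        chosen: Feature | None = None
        for p in result.placements:  # best-score first
            tree = trees.get(p.contig)
            if tree is None:
                continue
            overlaps = tree.overlap(p.start, p.end)
            if not overlaps:
                continue
            chosen = min(
                (iv.data for iv in overlaps),
                key=lambda f: (
                    -(min(f.end, p.end) - max(f.start, p.start)),
                    _CATEGORY_PRIORITY[f.category],
                    f.start,
                    f.feature_id,
                ),
            )
            break
        if chosen is None:
            if params.exclude_intergenic:
                summary.unmapped += 1
            else:
                summary.intergenic += 1
            continue
        multi = len(result.placements) > 1
        summary.per_feature[chosen.feature_id][1 if multi else 0] += 1
        if chosen.category == "tRNA":
            summary.trna += 1
        elif chosen.category == "rRNA":
            summary.rrna += 1
        elif multi:
            summary.cds_multi += 1
        else:
            summary.cds_unique += 1
    logger.info(
        "counted %d reads: tRNA=%d rRNA=%d CDS(unique)=%d CDS(multi)=%d unmapped=%d",
        summary.total_reads, summary.trna, summary.rrna,
        summary.cds_unique, summary.cds_multi, summary.unmapped,
    )
    return summary


def multiread_proportion(summary: CountSummary) -> float:
    """CDS multi-mapped reads as a percentage of all input reads."""
    if summary.total_reads == 0:
        logger.warning("multiread proportion of an empty library is undefined; returning 0")
        return 0.0
    return 100.0 * summary.cds_multi / summary.total_reads
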