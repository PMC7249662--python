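"""Cross-mapping quantification and confusion-matrix benchmarking of the
partitioning strategies: per-organism TP/FP/TN/FN and the derived
sensitivity, specificity, accuracy and precision.

Semantics: for organism O, TP = truth O and assigned O; FN = truth O but
assigned to the other organism; FP = assigned O but true origin the other
organism; TN = both the other organism. Reads removed as unmapped or
ambiguous are excluded from every denominator and reported separately.
Under this convention accuracy is identical for the two organisms of a
pair, and sensitivity of one equals specificity of the other.

A built-in fixture (:data:`TABLE1_COUNTS`) carries the printed accounting
of the published maize (Zea mays) / Herbaspirillum seropedicae chimera
benchmark, so the full strategy-comparison report can be reproduced in
closed form without any mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .feature_count import CountParams, CountSummary, count_reads
from .mapper import KmerIndex, MappingParams, build_index, map_read
from .reference_io import Feature, Genome, SequencedRead, UsageError, build_combined_reference
from .strategies import (
    UNMAPPED,
    AttributionTable,
    combined_partition,
    sequential_attribution_counts,
    sequential_partition,
)

logger = logging.getLogger("dualmap.evaluation")

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-organism confusion counts; the paired organism's counts are the
    same four numbers with TP<->TN and FP<->FN swapped."""

    organism: str
    tp: int
    fp: int
    tn: int
    fn: int
    excluded_unmapped: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.excluded_unmapped) < 0:
            raise UsageError("confusion counts must be non-negative")

    def swapped(self, organism: str) -> "ConfusionCounts":
        return ConfusionCounts(
            organism, tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp,
            excluded_unmapped=self.excluded_unmapped,
        )


def _round4(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/specificity/accuracy/precision, full precision.
    Undefined metrics (zero denominator) are NaN, never silently 0."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float

    def rounded(self) -> "MetricSet":
        """Half-up 4-decimal rounding, the print format of the published
        comparison tables."""
        return MetricSet(*(_round4(getattr(self, m)) for m in METRIC_NAMES))

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Derive the four benchmark metrics from one organism's confusion
    counts. Zero-denominator metrics come back as NaN with a warning."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined for %s (zero denominator)", name, c.organism)
            return float("nan")
        return num / den

    return MetricSet(
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        accuracy=ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "accuracy"),
        precision=ratio(c.tp, c.tp + c.fp, "precision"),
    )


def cross_tabulate(
    table: AttributionTable, organisms: tuple[str, str] | None = None
) -> tuple[ConfusionCounts, ConfusionCounts]:
    """Confusion counts for both organisms from a truth-labelled
    attribution table. Reads assigned unmapped (removed/ambiguous) are
    excluded and counted in ``excluded_unmapped``."""
    if organisms is None:
        orgs = sorted(
            {r.truth for r in table.rows if r.truth is not None}
            | {r.assigned for r in table.rows if r.assigned != UNMAPPED}
        )
        if len(orgs) != 2:
            raise UsageError(f"expected exactly two organisms, found {orgs}")
        organisms = (orgs[0], orgs[1])
    org_a, org_b = organisms
    tp = fp = tn = fn = excluded = 0
    for row in table.rows:
        if row.truth is None:
            raise UsageError(f"read {row.read_id!r} has no truth label")
        if row.assigned == UNMAPPED:
            excluded += 1
        elif row.truth == org_a and row.assigned == org_a:
            tp += 1
        elif row.truth == org_a and row.assigned == org_b:
            fn += 1
        elif row.truth == org_b and row.assigned == org_a:
            fp += 1
        elif row.truth == org_b and row.assigned == org_b:
            tn += 1
        else:
            raise UsageError(
                f"read {row.read_id!r}: labels ({row.truth}, {row.assigned}) "
                f"outside organisms {organisms}"
            )
    first = ConfusionCounts(org_a, tp=tp, fp=fp, tn=tn, fn=fn, excluded_unmapped=excluded)
    return first, first.swapped(org_b)


def crossmap_assay(
    reads: Iterable[SequencedRead],
    foreign: Genome,
    params: MappingParams = MappingParams(),
    *,
    index: KmerIndex | None = None,
) -> int:
    """Number of reads of a single-organism library with at least one
    admissible placement on the *other* organism's genome."""
    idx = index or build_index(foreign, params.kmer_size)
    return sum(1 for read in reads if map_read(read, idx, params).placements)


# ---------------------------------------------------------------------------
# Closed-form report from printed accounting (built-in fixture)
# ---------------------------------------------------------------------------

#: Printed accounting of the published maize/Herbaspirillum chimera
#: benchmark: direct-mapping-filtered library sizes, cross-mapping counts,
#: and the per-library outcome of mapping each filtered library to the
#: combined reference. Organism A is the prokaryote (H. seropedicae),
#: organism B the eukaryote (Z. mays).
TABLE1_COUNTS: dict[str, object] = {
    "organisms": ("H_seropedicae", "Z_mays"),
    "library_sizes": (44_469_308, 22_200_875),
    "cross_a_to_b": 13_847_693,
    "cross_b_to_a": 7_659,
    "combined": {
        "a_to_a": 43_661_668,
        "a_to_b": 779_556,
        "a_unmapped": 28_084,
        "b_to_a": 394,
        "b_to_b": 22_200_465,
        "b_unmapped": 16,
    },
}


@dataclass(frozen=True)
class ClosedFormReport:
    """Attribution totals and metrics for the three strategies, derived in
    closed form from printed library/cross-mapping counts."""

    organisms: tuple[str, str]
    attributions: dict[str, dict[str, int]]
    confusions: dict[str, tuple[ConfusionCounts, ConfusionCounts]]
    metrics: dict[str, dict[str, MetricSet]]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for metric in METRIC_NAMES:
            row: dict[str, object] = {"metric": metric}
            for strategy, per_org in self.metrics.items():
                for org, mset in per_org.items():
                    row[f"{strategy}:{org}"] = getattr(mset.rounded(), metric)
            rows.append(row)
        return pd.DataFrame(rows)


def closed_form_report(counts: Mapping[str, object] = TABLE1_COUNTS) -> ClosedFormReport:
    """Reproduce the full strategy-comparison accounting from printed
    counts: sequential attribution in both orders via the closed-form rule,
    combined attribution from the per-library combined-reference outcomes,
    and all metric cells from the implied confusion matrices.

    The chimera is assumed pre-filtered by direct mapping, so under
    sequential analysis every read maps at least to its own genome and no
    reads are unmapped; under combined analysis the unmapped/ambiguous
    reads are excluded from all metric denominators.
    """
    org_a, org_b = counts["organisms"]  # type: ignore[misc]
    n_a, n_b = counts["library_sizes"]  # type: ignore[misc]
    cross_ab = int(counts["cross_a_to_b"])  # type: ignore[arg-type]
    cross_ba = int(counts["cross_b_to_a"])  # type: ignore[arg-type]
    comb: Mapping[str, int] = counts["combined"]  # type: ignore[assignment]

    attributions = {
        "sequential_B_first": sequential_attribution_counts(
            n_a, n_b, cross_ab, cross_ba, "B_first", (org_a, org_b)
        ),
        "sequential_A_first": sequential_attribution_counts(
            n_a, n_b, cross_ab, cross_ba, "A_first", (org_a, org_b)
        ),
        "combined": {
            org_a: comb["a_to_a"] + comb["b_to_a"],
            org_b: comb["a_to_b"] + comb["b_to_b"],
            UNMAPPED: comb["a_unmapped"] + comb["b_unmapped"],
        },
    }
    confusions = {
        # B (eukaryote) first: every A read admissible on B goes to B.
        "sequential_B_first": ConfusionCounts(
            org_a, tp=n_a - cross_ab, fp=0, tn=n_b, fn=cross_ab
        ),
        # A (prokaryote) first: every B read admissible on A goes to A.
        "sequential_A_first": ConfusionCounts(
            org_a, tp=n_a, fp=cross_ba, tn=n_b - cross_ba, fn=0
        ),
        "combined": ConfusionCounts(
            org_a,
            tp=comb["a_to_a"],
            fn=comb["a_to_b"],
            fp=comb["b_to_a"],
            tn=comb["b_to_b"],
            excluded_unmapped=comb["a_unmapped"] + comb["b_unmapped"],
        ),
    }
    pairs = {
        name: (c, c.swapped(org_b)) for name, c in confusions.items()
    }
    metrics = {
        name: {org_a: compute_metrics(a), org_b: compute_metrics(b)}
        for name, (a, b) in pairs.items()
    }
    return ClosedFormReport((org_a, org_b), attributions, pairs, metrics)


# ---------------------------------------------------------------------------
# End-to-end strategy comparison
# ---------------------------------------------------------------------------

@dataclass
class StrategyReport:
    strategy: str
    table: AttributionTable
    confusion: tuple[ConfusionCounts, ConfusionCounts]
    metrics: dict[str, MetricSet]
    counts: dict[str, CountSummary] = field(default_factory=dict)


@dataclass
class StrategyComparison:
    """Reports for all three strategies on one truth-tagged library."""

    organisms: tuple[str, str]
    reports: dict[str, StrategyReport]

    def attribution_frame(self) -> pd.DataFrame:
        """Attribution totals per strategy (the top of a comparison table)."""
        org_a, org_b = self.organisms
        rows = []
        for name, rep in self.reports.items():
            totals = rep.table.totals()
            rows.append(
                {
                    "strategy": name,
                    org_a: totals.get(org_a, 0),
                    org_b: totals.get(org_b, 0),
                    UNMAPPED: totals.get(UNMAPPED, 0),
                }
            )
        return pd.DataFrame(rows)

    def metrics_frame(self) -> pd.DataFrame:
        """Metric cells per strategy and organism (the bottom rows of a
        comparison table), rounded half-up to 4 decimals."""
        rows = []
        for metric in METRIC_NAMES:
            row: dict[str, object] = {"metric": metric}
            for name, rep in self.reports.items():
                for org, mset in rep.metrics.items():
                    row[f"{name}:{org}"] = getattr(mset.rounded(), metric)
            rows.append(row)
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        """Category counts per strategy and organism (count-table shape)."""
        rows = []
        for name, rep in self.reports.items():
            for org, summary in rep.counts.items():
                rows.append({"strategy": name, "organism": org, **summary.to_row()})
        return pd.DataFrame(rows)


def compare_strategies(
    reads: Sequence[SequencedRead],
    genome_a: Genome,
    genome_b: Genome,
    params: MappingParams = MappingParams(),
    tie_margin: float = 0.0,
    features: Mapping[str, Sequence[Feature]] | None = None,
    count_params: CountParams | None = None,
) -> StrategyComparison:
    """Run both sequential orders and the combined strategy on a
    truth-tagged library, cross-tabulate each against the truth tags, and
    compute all metrics. If per-organism annotations are supplied, the
    per-organism extracts are also counted (count-table shape)."""
    org_a, org_b = genome_a.organism_id, genome_b.organism_id
    idx_a = build_index(genome_a, params.kmer_size)
    idx_b = build_index(genome_b, params.kmer_size)
    combined = build_combined_reference(genome_a, genome_b)
    idx_c = build_index(combined, params.kmer_size)

    tables = {
        f"sequential_{org_a}_first": sequential_partition(
            reads, genome_a, genome_b, params,
            first_index=idx_a, second_index=idx_b,
        ),
        f"sequential_{org_b}_first": sequential_partition(
            reads, genome_b, genome_a, params,
            first_index=idx_b, second_index=idx_a,
        ),
        "combined": combined_partition(
            reads, combined, params, tie_margin, index=idx_c
        ),
    }
    reports: dict[str, StrategyReport] = {}
    for name, table in tables.items():
        conf = cross_tabulate(table, (org_a, org_b))
        metrics = {org_a: compute_metrics(conf[0]), org_b: compute_metrics(conf[1])}
        report = StrategyReport(name, table, conf, metrics)
        if features is not None:
            cp = count_params or CountParams(
                min_length_fraction=params.min_length_fraction,
                min_similarity_fraction=params.min_similarity_fraction,
            )
            assigned = {r.read_id: r.assigned for r in table.rows}
            for genome, idx in ((genome_a, idx_a), (genome_b, idx_b)):
                org = genome.organism_id
                extract = [r for r in reads if assigned[r.name] == org]
                report.counts[org] = count_reads(
                    extract, genome, features[org], cp, index=idx
                )
        reports[name] = report
    return StrategyComparison((org_a, org_b), reports)
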