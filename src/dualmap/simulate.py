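"""Synthetic dual-organism data: a eukaryote-like / prokaryote-like genome
pair with controllable shared (homologous) tracts, annotated tRNA/rRNA/CDS
features, and truth-tagged read libraries mixed into a chimera library.

The generator emulates the statistical structure a dual RNA-seq
partitioning analysis assumes: two genomes whose only sequence similarity
is the configured homologous tracts (by default one rRNA-like tract, the
dominant real-world source of cross-mapping), feature-shaped expression
with one dominant rRNA locus per organism, and reads whose names encode
their true origin so attribution can be scored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference_io import (
    Contig,
    Feature,
    Genome,
    SequencedRead,
    UsageError,
    reverse_complement,
)

logger = logging.getLogger("dualmap.simulate")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Truth tags are encoded in read names as
#   <origin>|<feature_id>|<contig>|<start>|<serial>[/<mate>]
_TAG_FIELDS = 5


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic dual-organism experiment.

    genome_lengths: eukaryote-like and prokaryote-like genome sizes (bp).
    n_features: per-organism, per-category feature counts ("A" = eukaryote).
    homology: (length, divergence) tracts copied from organism A into B;
        the first tract is realised as a shared rRNA-like locus in both
        genomes. Divergence is the per-base substitution probability.
    depth: median reads per feature; per-feature counts are log-normal with
        dispersion ``depth_sigma``; the first rRNA of each organism is
        boosted ``rrna_boost``-fold to mimic rRNA-dominated libraries.
    mix_ratio: if set, fraction of the organism-A library retained when
        building the chimera.
    """

    seed: int = 0
    genome_lengths: tuple[int, int] = (200_000, 50_000)
    n_features: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "A": {"CDS": 40, "tRNA": 8, "rRNA": 2},
            "B": {"CDS": 30, "tRNA": 6, "rRNA": 2},
        }
    )
    organisms: tuple[str, str] = ("euk", "prok")
    homology: tuple[tuple[int, float], ...] = ((1500, 0.05),)
    read_length: int = 75
    substitution_error: float = 0.005
    depth: float = 25.0
    depth_sigma: float = 0.7
    rrna_boost: float = 20.0
    mix_ratio: float | None = None
    paired: bool = False
    insert_mean: float = 250.0
    insert_sd: float = 30.0

    def __post_init__(self) -> None:
        for _length, div in self.homology:
            if not (0.0 <= div <= 1.0):
                raise UsageError(f"homology divergence {div} outside [0, 1]")
        if self.read_length < 20:
            raise UsageError("read_length below the 20 nt trimming floor")


@dataclass(frozen=True)
class TruthTag:
    """Ground-truth origin of a simulated read, parsed from its name."""

    origin: str
    feature_id: str
    contig: str
    start: int
    serial: int
    mate: int | None = None


def parse_truth_tag(read_name: str) -> TruthTag | None:
    """Decode a truth tag from a read name; None if the name carries none."""
    name = read_name.split()[0]
    mate: int | None = None
    if name.endswith(("/1", "/2")):
        mate = int(name[-1])
        name = name[:-2]
    fields = name.split("|")
    if len(fields) != _TAG_FIELDS:
        return None
    try:
        return TruthTag(fields[0], fields[1], fields[2], int(fields[3]), int(fields[4]), mate)
    except ValueError:
        return None


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a different base."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _feature_lengths(
    counts: Mapping[str, int], rng: np.random.Generator, rrna_length: int
) -> list[tuple[str, int]]:
    lengths: list[tuple[str, int]] = []
    for i in range(counts.get("rRNA", 0)):
        lengths.append(("rRNA", rrna_length if i == 0 else 1500))
    for _ in range(counts.get("tRNA", 0)):
        lengths.append(("tRNA", int(rng.integers(70, 91))))
    for _ in range(counts.get("CDS", 0)):
        lengths.append(("CDS", int(rng.integers(300, 1501))))
    return lengths


def _place_features(
    org: str,
    contig_name: str,
    genome_length: int,
    lengths: Sequence[tuple[str, int]],
    rng: np.random.Generator,
    spacing: int = 50,
) -> list[Feature]:
    """Place features non-overlapping, in random order, with >= ``spacing``
    bp between consecutive features, random gaps, random strands."""
    order = rng.permutation(len(lengths))
    total = sum(length for _c, length in lengths)
    slack = genome_length - total - spacing * (len(lengths) + 1)
    if slack < 0:
        raise UsageError(
            f"{org}: features ({total} bp + spacing) exceed genome length {genome_length}"
        )
    # distribute the slack over the n+1 gaps
    extra = rng.multinomial(slack, np.ones(len(lengths) + 1) / (len(lengths) + 1))
    counters: dict[str, int] = {}
    features: list[Feature] = []
    pos = spacing + int(extra[0])
    for slot, oi in enumerate(order):
        category, length = lengths[oi]
        counters[category] = counters.get(category, 0) + 1
        fid = f"{org}_{category.lower()}_{counters[category]:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(contig_name, pos, pos + length, strand, category, fid))
        pos += length + spacing + int(extra[slot + 1])
    return sorted(features, key=lambda f: f.start)


def simulate_genome_pair(
    params: SimParams = SimParams(),
) -> tuple[Genome, Genome, list[Feature], list[Feature]]:
    """Generate the two genomes and their annotations.

    Backgrounds are i.i.d. uniform nucleotides, so the only homology between
    the genomes is the configured shared tracts. Tract 0 is copied from
    organism A's first rRNA locus over organism B's first rRNA locus (both
    loci are given the tract's length); any further tract i is copied from
    A's i-th CDS into B's i-th CDS. Fully deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed)
    org_a, org_b = params.organisms
    len_a, len_b = params.genome_lengths
    rrna_len = params.homology[0][0] if params.homology else 1500
    feats: dict[str, list[Feature]] = {}
    arrays: dict[str, np.ndarray] = {}
    contig_names = {org_a: f"{org_a}_chr1", org_b: f"{org_b}_chr1"}
    for org, key, glen in ((org_a, "A", len_a), (org_b, "B", len_b)):
        lengths = _feature_lengths(params.n_features[key], rng, rrna_len)
        feats[org] = _place_features(org, contig_names[org], glen, lengths, rng)
        arrays[org] = _random_sequence(rng, glen)

    def first_of(org: str, category: str, nth: int = 0) -> Feature:
        matching = [f for f in feats[org] if f.category == category]
        if nth >= len(matching):
            raise UsageError(
                f"homology tract {nth} needs a {category} feature in {org!r}"
            )
        return sorted(matching, key=lambda f: f.feature_id)[nth]

    for i, (length, divergence) in enumerate(params.homology):
        if i == 0:
            src = first_of(org_a, "rRNA")
            dst = first_of(org_b, "rRNA")
        else:
            src = first_of(org_a, "CDS", i - 1)
            dst = first_of(org_b, "CDS", i - 1)
        span = min(length, len(src), len(dst))
        tract = arrays[org_a][src.start : src.start + span]
        arrays[org_b][dst.start : dst.start + span] = _mutate(tract, divergence, rng)

    genome_a = Genome(org_a, [Contig(contig_names[org_a], arrays[org_a].tobytes().decode("ascii"))])
    genome_b = Genome(org_b, [Contig(contig_names[org_b], arrays[org_b].tobytes().decode("ascii"))])
    return genome_a, genome_b, feats[org_a], feats[org_b]


def simulate_reads(
    genome: Genome,
    features: Sequence[Feature],
    params: SimParams = SimParams(),
    stream: int = 0,
) -> tuple[list[SequencedRead], dict[str, int]]:
    """Simulate a truth-tagged library from one genome's features.

    Per-feature read counts are log-normal around ``params.depth`` (the
    first rRNA locus boosted ``rrna_boost``-fold); read starts are uniform
    within the feature; substitution errors are i.i.d.; qualities are
    constant. Returns the reads and the per-feature counts actually drawn.
    ``stream`` decorrelates the two organisms' libraries under one seed.
    """
    if not features:
        raise UsageError("no features to simulate reads from")
    rng = np.random.default_rng([params.seed, stream])
    contig_arrays = {
        c.name: np.frombuffer(c.sequence.encode("ascii"), dtype=np.uint8)
        for c in genome.contigs
    }
    boosted = min(
        (f for f in features if f.category == "rRNA"),
        key=lambda f: f.feature_id,
        default=None,
    )
    reads: list[SequencedRead] = []
    drawn: dict[str, int] = {}
    serial = 0
    for feat in features:
        depth = params.depth * (params.rrna_boost if feat is boosted else 1.0)
        count = int(round(rng.lognormal(mean=math.log(depth), sigma=params.depth_sigma)))
        read_len = min(params.read_length, len(feat))
        if read_len < 20:
            logger.warning("feature %s shorter than 20 nt; skipped", feat.feature_id)
            drawn[feat.feature_id] = 0
            continue
        drawn[feat.feature_id] = count
        arr = contig_arrays[feat.contig]
        for _ in range(count):
            if params.paired:
                frag = int(round(rng.normal(params.insert_mean, params.insert_sd)))
                frag = max(read_len, min(frag, len(feat)))
                start = int(rng.integers(feat.start, feat.end - frag + 1))
                frag_seq = _mutate(arr[start : start + frag], params.substitution_error, rng)
                if feat.strand == "-":
                    frag_seq = np.frombuffer(
                        reverse_complement(frag_seq.tobytes().decode("ascii")).encode("ascii"),
                        dtype=np.uint8,
                    )
                m1 = frag_seq[:read_len].tobytes().decode("ascii")
                m2 = reverse_complement(frag_seq[-read_len:].tobytes().decode("ascii"))
                base = f"{genome.organism_id}|{feat.feature_id}|{feat.contig}|{start}|{serial}"
                qual = "I" * read_len
                reads.append(SequencedRead(f"{base}/1", m1, qual))
                reads.append(SequencedRead(f"{base}/2", m2, qual))
            else:
                start = int(rng.integers(feat.start, feat.end - read_len + 1))
                seq_arr = _mutate(arr[start : start + read_len], params.substitution_error, rng)
                seq = seq_arr.tobytes().decode("ascii")
                if feat.strand == "-":
                    seq = reverse_complement(seq)
                name = f"{genome.organism_id}|{feat.feature_id}|{feat.contig}|{start}|{serial}"
                reads.append(SequencedRead(name, seq, "I" * read_len))
            serial += 1
    return reads, drawn


def make_chimera(
    lib_a: Sequence[SequencedRead],
    lib_b: Sequence[SequencedRead],
    mix_ratio: float | None = None,
    seed: int = 0,
) -> list[SequencedRead]:
    """Merge two truth-tagged libraries into a chimera library.

    If ``mix_ratio`` is given, a deterministic subsample of
    round(mix_ratio * len(lib_a)) reads is taken from ``lib_a``. The merged
    library is shuffled deterministically under ``seed``; read names (and
    so truth tags) are preserved.
    """
    rng = np.random.default_rng(seed)
    a = list(lib_a)
    if mix_ratio is not None:
        if not (0.0 <= mix_ratio <= 1.0):
            raise UsageError(f"mix_ratio {mix_ratio} outside [0, 1]")
        keep = int(round(mix_ratio * len(a)))
        idx = sorted(rng.choice(len(a), size=keep, replace=False))
        a = [a[i] for i in idx]
    merged = a + list(lib_b)
    order = rng.permutation(len(merged))
    return [merged[i] for i in order]
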