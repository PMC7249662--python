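"""Reference and read I/O: FASTA genomes, GFF3 annotations, FASTQ libraries,
and the combined (concatenated) two-organism reference with contig provenance.

All genomic intervals are held internally as 0-based, half-open coordinates;
GFF3's 1-based inclusive convention is converted at the parsing boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("dualmap.reference_io")

VALID_BASES = frozenset("ACGTN")
FEATURE_CATEGORIES = ("tRNA", "rRNA", "CDS")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DualMapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DualMapError):
    """A file does not conform to its declared format."""


class UsageError(DualMapError):
    """An operation was invoked with inconsistent or invalid arguments."""


class ConsistencyError(DualMapError):
    """Two inputs that must agree (e.g. reads vs attribution table) do not."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("contig name must be non-empty")
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.name!r} has an empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise FormatError(f"contig {self.name!r} contains invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of contigs belonging to one organism."""

    organism_id: str
    contigs: list[Contig]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError(f"genome {self.organism_id!r} has no contigs")
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate contig names in {self.organism_id!r}: {dupes}")
        self._by_name = {c.name: c for c in self.contigs}

    def __len__(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, name: str) -> Contig:
        return self._by_name[name]

    @property
    def contig_names(self) -> list[str]:
        return [c.name for c in self.contigs]


@dataclass
class CombinedReference:
    """Contigs of two organisms plus a contig -> organism provenance map.

    This is the "chimeric" concatenated reference used by the combined
    partitioning strategy; provenance lets every placement be attributed
    back to its source organism.
    """

    contigs: list[Contig]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise FormatError("combined reference has duplicate contig names")
        if set(names) != set(self.provenance):
            raise FormatError("provenance map does not cover the combined contigs exactly")
        orgs = sorted(set(self.provenance.values()))
        if len(orgs) != 2:
            raise UsageError(f"combined reference must span exactly two organisms, got {orgs}")
        self._by_name = {c.name: c for c in self.contigs}

    def __len__(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, name: str) -> Contig:
        return self._by_name[name]

    @property
    def organisms(self) -> tuple[str, str]:
        """The two organism ids, in first-appearance order."""
        seen: list[str] = []
        for c in self.contigs:
            org = self.provenance[c.name]
            if org not in seen:
                seen.append(org)
        return (seen[0], seen[1])


@dataclass(frozen=True)
class Feature:
    """An annotated locus (0-based, half-open) of a counted category."""

    contig: str
    start: int
    end: int
    strand: str
    category: str
    feature_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.feature_id!r}: unknown strand {self.strand!r}")
        if self.category not in FEATURE_CATEGORIES:
            raise FormatError(
                f"feature {self.feature_id!r}: category {self.category!r} is not counted"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SequencedRead:
    """One FASTQ record. The name is preserved verbatim (it may carry a
    simulator truth tag encoding the read's true origin)."""

    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.name!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(b if b in VALID_BASES else "N" for b in seq)


def read_fasta(path: str | Path, organism_id: str | None = None) -> Genome:
    """Load a FASTA file as a Genome.

    Sequences are upper-cased and any character outside {A,C,G,T,N} is
    mapped to N. The organism id defaults to the file stem.
    """
    path = Path(path)
    if organism_id is None:
        organism_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seen:
                raise FormatError(f"{path}: duplicate contig name {record.id!r}")
            seen.add(record.id)
            contigs.append(Contig(record.id, _sanitize(str(record.seq))))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(organism_id, contigs)


def write_fasta(reference: Genome | CombinedReference, path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in reference.contigs]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Combined reference
# ---------------------------------------------------------------------------

def build_combined_reference(a: Genome, b: Genome) -> CombinedReference:
    """Concatenate two genomes into a combined reference with provenance.

    Mirrors merging two genome FASTA files with ``cat``, except that contig
    name collisions are made explicit: any name present in both genomes is
    prefixed with ``<organism_id>|`` on both sides, so a collision can never
    silently merge two contigs.
    """
    if a.organism_id == b.organism_id:
        raise UsageError(f"both genomes claim organism id {a.organism_id!r}")
    collisions = set(a.contig_names) & set(b.contig_names)
    if collisions:
        logger.warning(
            "contig name collision(s) %s; prefixing with organism id", sorted(collisions)
        )
    contigs: list[Contig] = []
    provenance: dict[str, str] = {}
    for genome in (a, b):
        for c in genome.contigs:
            name = f"{genome.organism_id}|{c.name}" if c.name in collisions else c.name
            contigs.append(Contig(name, c.sequence))
            provenance[name] = genome.organism_id
    return CombinedReference(contigs, provenance)


def provenance_sidecar_path(fasta_path: str | Path) -> Path:
    return Path(str(fasta_path) + ".provenance.tsv")


def write_combined_reference(combined: CombinedReference, fasta_path: str | Path) -> None:
    """Write the combined FASTA plus a 2-column provenance TSV sidecar next to
    it, so provenance survives export to third-party mappers."""
    write_fasta(combined, fasta_path)
    with open(provenance_sidecar_path(fasta_path), "w") as fh:
        fh.write("contig\torganism\n")
        for c in combined.contigs:
            fh.write(f"{c.name}\t{combined.provenance[c.name]}\n")


def read_combined_reference(
    fasta_path: str | Path, provenance_path: str | Path | None = None
) -> CombinedReference:
    if provenance_path is None:
        provenance_path = provenance_sidecar_path(fasta_path)
    genome = read_fasta(fasta_path)
    provenance: dict[str, str] = {}
    with open(provenance_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["contig", "organism"]:
            raise FormatError(f"{provenance_path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{provenance_path}: malformed line {line!r}")
            provenance[fields[0]] = fields[1]
    return CombinedReference(genome.contigs, provenance)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(
    path: str | Path, categories: Iterable[str] = FEATURE_CATEGORIES
) -> list[Feature]:
    """Parse a GFF3 file, keeping only rows whose type column is in
    ``categories``. File coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention."""
    wanted = set(categories)
    unknown = wanted - set(FEATURE_CATEGORIES)
    if unknown:
        raise UsageError(f"unknown feature categories {sorted(unknown)}")
    features: list[Feature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            if start < 1:
                raise FormatError(f"{path}:{lineno}: GFF3 coordinates are 1-based")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            feature_id = (
                _gff3_attribute(attrs, "ID")
                or _gff3_attribute(attrs, "locus_tag")
                or f"{ftype}:{contig}:{start}"
            )
            features.append(Feature(contig, start - 1, end, strand, ftype, feature_id))
    return features


def write_gff3(features: Sequence[Feature], path: str | Path, source: str = "dualmap") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\t{source}\t{f.category}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream a FASTQ file. An empty file yields an empty stream; a truncated
    or malformed record raises :class:`FormatError`."""
    with _open_text(path) as fh:
        try:
            for record in SeqIO.parse(fh, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in record.letter_annotations["phred_quality"]
                )
                yield SequencedRead(record.description or record.id, str(record.seq), qual)
        except ValueError as exc:  # Biopython's FASTQ parse errors
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> int:
    """Write reads to FASTQ, preserving names verbatim. Returns the number of
    reads written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            record = SeqRecord(Seq(read.sequence), id=read.name, description="")
            record.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in read.quality
            ]
            SeqIO.write(record, fh, "fastq")
            n += 1
    return n


def trim_short_reads(
    reads: Iterable[SequencedRead], min_length: int = 20
) -> Iterator[SequencedRead]:
    """Drop reads shorter than ``min_length`` nucleotides (the trimming
    floor applied before mapping). Quality-based trimming is out of scope."""
    for read in reads:
        if len(read) >= min_length:
            yield read
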