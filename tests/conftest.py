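"""Shared fixtures: small deterministic genomes, reads and annotations
built programmatically (no data files)."""

from __future__ import annotations

import numpy as np
import pytest

from dualmap import Contig, Feature, Genome, SequencedRead

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def mutate_positions(seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = FLIP[out[p]]
    return "".join(out)


def as_read(name: str, seq: str) -> SequencedRead:
    return SequencedRead(name, seq, "I" * len(seq))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """A 3 kb single-contig genome, fixed seed."""
    r = np.random.default_rng(11)
    return Genome("orgA", [Contig("c1", random_seq(r, 3000))])


@pytest.fixture(scope="session")
def genome_pair() -> tuple[Genome, Genome]:
    """Two unrelated 2 kb genomes sharing one identical 300 bp tract
    (planted at A[600:900] == B[1000:1300])."""
    r = np.random.default_rng(13)
    a = random_seq(r, 2000)
    b_list = list(random_seq(r, 2000))
    b_list[1000:1300] = a[600:900]
    return (
        Genome("orgA", [Contig("chrA", a)]),
        Genome("orgB", [Contig("chrB", "".join(b_list))]),
    )
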