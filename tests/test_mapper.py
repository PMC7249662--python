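"""Seed-and-extend mapper: index construction, the fraction-based
acceptance contract, placement determinism, pairing, and agreement with
the brute-force alignment oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualmap import (
    Contig,
    Genome,
    MappingParams,
    UsageError,
    align_extend,
    build_index,
    map_pair,
    map_read,
    reverse_complement,
    write_sam,
)
from dualmap.mapper import _local_align

from conftest import FLIP, as_read, mutate_positions, random_seq
from oracle import oracle_placements, plain_local_align

PARAMS = MappingParams()


class TestIndex:
    def test_kmer_positions(self):
        g = Genome("o", [Contig("c1", "ACGTACGTACGT")])
        idx = build_index(g, 8)
        assert {(c, p) for c, p, s in idx.lookup("ACGTACGT") if s == "+"} == {
            ("c1", 0), ("c1", 4)
        }

    def test_reverse_complement_hits_minus_strand(self):
        g = Genome("o", [Contig("c1", "AACCGGTTAACC")])
        idx = build_index(g, 8)
        km = "AACCGGTT"
        assert ("c1", 0, "+") in idx.lookup(km)
        assert ("c1", 0, "-") in idx.lookup(reverse_complement(km))

    def test_combined_index_is_union_with_provenance(self, genome_pair):
        from dualmap import build_combined_reference

        a, b = genome_pair
        idx_a = build_index(a, 12)
        idx_b = build_index(b, 12)
        idx_c = build_index(build_combined_reference(a, b), 12)
        assert idx_c.provenance["chrA"] == "orgA" and idx_c.provenance["chrB"] == "orgB"
        for km in list(idx_a.index)[:200]:
            merged = set(idx_a.lookup(km)) | set(idx_b.lookup(km))
            assert set(idx_c.lookup(km)) == merged

    def test_small_k_rejected(self, small_genome):
        with pytest.raises(UsageError):
            build_index(small_genome, 7)


class TestAlignExtend:
    def test_exact_substring_is_perfect(self, small_genome):
        c = small_genome.contigs[0]
        p = align_extend(c.sequence[700:760], c, 700, "+", PARAMS)
        assert p is not None
        assert p.length_fraction == 1.0 and p.similarity_fraction == 1.0
        assert (p.start, p.end) == (700, 760)

    def test_similarity_threshold_boundary(self, small_genome):
        """20-base read: 4 internal mismatches sit exactly at the 0.8
        similarity threshold; a fifth pushes it below and is rejected."""
        c = small_genome.contigs[0]
        read4 = mutate_positions(c.sequence[100:120], (3, 7, 11, 15))
        p = align_extend(read4, c, 100, "+", PARAMS)
        assert p is not None
        assert p.similarity_fraction == pytest.approx(0.8)
        read5 = mutate_positions(read4, (5,))
        assert align_extend(read5, c, 100, "+", PARAMS) is None

    def test_seed_outside_contig_rejected(self, small_genome):
        with pytest.raises(UsageError):
            align_extend("ACGT" * 10, small_genome.contigs[0], 99999, "+", PARAMS)

    @pytest.mark.parametrize("trial", range(30))
    def test_extension_matches_textbook_dp(self, trial, rng):
        """The vectorized banded extension reproduces the score and
        alignment statistics of a plain nested-loop local aligner."""
        n = int(rng.integers(15, 41))
        m = int(rng.integers(40, 140))
        q = random_seq(rng, n)
        w = random_seq(rng, m)
        if trial % 2:  # plant the read so alignments are non-trivial
            pos = int(rng.integers(0, m - n + 1))
            w = w[:pos] + mutate_positions(q, rng.choice(n, 2, replace=False)) + w[pos + n:]
        got = _local_align(
            np.frombuffer(q.encode(), dtype=np.uint8),
            np.frombuffer(w.encode(), dtype=np.uint8),
        )
        expect = plain_local_align(q, w)
        if expect is None:
            assert got is None
        else:
            score, q0, q1, w0, w1, matches, columns = expect
            assert got.score == score
            assert (got.read_start, got.read_end) == (q0, q1)
            assert (got.ref_start, got.ref_end) == (w0, w1)
            assert (got.matches, got.columns) == (matches, columns)


class TestMapRead:
    def test_unique_multi_unmapped(self, rng):
        core = random_seq(rng, 800)
        repeat = core[100:175]
        ref = core + random_seq(rng, 300) + repeat + random_seq(rng, 200)
        g = Genome("o", [Contig("c1", ref)])
        idx = build_index(g, 15)
        assert map_read(repeat, idx, PARAMS).status == "multi"
        assert len(map_read(repeat, idx, PARAMS).placements) == 2
        assert map_read(core[300:375], idx, PARAMS).status == "unique"
        rand = random_seq(np.random.default_rng(999), 75)
        res = map_read(rand, idx, PARAMS)
        assert res.status == "unmapped"
        # confirmed absent by exhaustive scan
        assert oracle_placements(rand, g, PARAMS) == set()

    def test_short_read_unmapped(self, small_genome):
        idx = build_index(small_genome, 15)
        assert map_read("ACGTACGT", idx, PARAMS).status == "unmapped"

    def test_determinism(self, small_genome, rng):
        idx = build_index(small_genome, 15)
        read = small_genome.contigs[0].sequence[40:115]
        first = map_read(read, idx, PARAMS)
        for _ in range(3):
            again = map_read(read, idx, PARAMS)
            assert again.placements == first.placements
            assert again.status == first.status

    def test_strand_symmetry(self, small_genome, rng):
        """Mapping a read equals mapping its reverse complement with
        strands flipped."""
        idx = build_index(small_genome, 15)
        for start in (0, 333, 1500, 2900):
            read = small_genome.contigs[0].sequence[start : start + 75]
            if len(read) < 20:
                continue
            fwd = map_read(read, idx, PARAMS)
            rev = map_read(reverse_complement(read), idx, PARAMS)
            flip = {"+": "-", "-": "+"}
            assert {(p.contig, p.start, p.strand, p.score) for p in fwd.placements} == {
                (p.contig, p.start, flip[p.strand], p.score) for p in rev.placements
            }

    def test_threshold_monotonicity(self, small_genome, rng):
        """Raising either acceptance fraction never increases the number
        of admissible placements."""
        idx = build_index(small_genome, 15)
        reads = []
        seq = small_genome.contigs[0].sequence
        for i in range(40):
            start = int(rng.integers(0, len(seq) - 75))
            nmut = int(rng.integers(0, 4))
            muts = rng.choice(60, size=nmut, replace=False) if nmut else []
            reads.append(mutate_positions(seq[start : start + 75], muts))
        lax = MappingParams(0.8, 0.8, max_hits_reported=50)
        for strict in (MappingParams(0.9, 0.8, max_hits_reported=50),
                       MappingParams(0.8, 0.9, max_hits_reported=50)):
            for read in reads:
                n_lax = len(map_read(read, idx, lax).placements)
                n_strict = len(map_read(read, idx, strict).placements)
                assert n_strict <= n_lax


@pytest.fixture(scope="module")
def paired_setup():
    r = np.random.default_rng(21)
    seq = random_seq(r, 4000)
    g = Genome("o", [Contig("c1", seq), Contig("c2", random_seq(r, 1000))])
    return g, build_index(g, 15)


class TestMapPair:

    def test_proper_pair(self, paired_setup):
        g, idx = paired_setup
        seq = g.contigs[0].sequence
        m1 = seq[1000:1075]
        m2 = reverse_complement(seq[1175:1250])  # insert 250
        r1, r2 = map_pair(m1, m2, idx, MappingParams(paired=True))
        assert not r1.broken_pair and not r2.broken_pair
        assert r1.best.strand != r2.best.strand

    def test_mates_on_different_contigs_are_broken(self, paired_setup):
        g, idx = paired_setup
        m1 = g.contigs[0].sequence[500:575]
        m2 = reverse_complement(g.contigs[1].sequence[100:175])
        r1, r2 = map_pair(m1, m2, idx, MappingParams(paired=True))
        assert r1.placements and r2.placements
        assert r1.broken_pair and r2.broken_pair

    def test_one_mate_unmapped_is_broken(self, paired_setup):
        g, idx = paired_setup
        m1 = g.contigs[0].sequence[500:575]
        m2 = random_seq(np.random.default_rng(5), 75)
        r1, r2 = map_pair(m1, m2, idx, MappingParams(paired=True))
        assert r1.placements and not r2.placements
        assert r1.broken_pair and r2.broken_pair

    def test_insert_out_of_range_is_broken(self, paired_setup):
        g, idx = paired_setup
        seq = g.contigs[0].sequence
        m1 = seq[100:175]
        m2 = reverse_complement(seq[2000:2075])
        r1, r2 = map_pair(m1, m2, idx, MappingParams(paired=True, insert_range=(100, 500)))
        assert r1.broken_pair and r2.broken_pair


@settings(max_examples=30, derandomize=True, deadline=None)
@given(start=st.integers(0, 2900), nmut=st.integers(0, 2), data=st.data())
def test_planted_read_always_recovered(small_genome, start, nmut, data):
    """Property: a read copied from the genome with at most two
    substitutions is always mapped back to its source position."""
    seq = small_genome.contigs[0].sequence
    read = seq[start : min(start + 75, len(seq))]
    if len(read) < 30:
        read = seq[-75:]
        start = len(seq) - 75
    positions = data.draw(
        st.lists(st.integers(0, len(read) - 1), min_size=nmut, max_size=nmut, unique=True)
    )
    read = mutate_positions(read, positions)
    idx = build_index(small_genome, 15)
    res = map_read(read, idx, MappingParams())
    # terminal mutations may be soft-clipped, shifting the reported start;
    # the placement must still cover most of the planted interval
    assert any(
        min(p.end, start + 75) - max(p.start, start) >= 60 for p in res.placements
    )


def test_sam_output_parses_with_pysam(tmp_path, small_genome):
    pysam = pytest.importorskip("pysam")
    idx = build_index(small_genome, 15)
    seq = small_genome.contigs[0].sequence
    reads = [
        as_read("r1", seq[100:175]),
        as_read("r2", reverse_complement(seq[500:575])),
        as_read("r3", random_seq(np.random.default_rng(3), 75)),
    ]
    results = [(r, map_read(r, idx, PARAMS)) for r in reads]
    sam = tmp_path / "out.sam"
    write_sam(results, idx, str(sam))
    with pysam.AlignmentFile(str(sam), "r") as fh:
        records = list(fh)
    by_name = {r.query_name: r for r in records}
    assert by_name["r1"].reference_start == 100
    assert by_name["r1"].get_tag("NH") == 1
    assert by_name["r1"].get_tag("XO") == "orgA"
    assert by_name["r2"].is_reverse and by_name["r2"].reference_start == 500
    assert by_name["r3"].is_unmapped
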