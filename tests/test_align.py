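"""Aligner: DP oracle parity (biotite), seed-and-extend recovery, SAM I/O."""

from __future__ import annotations

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transgenemap.align import (
    AlignerError,
    InsertModel,
    ScoringScheme,
    align_end_to_end,
    align_local,
    align_pairs,
    build_index,
    parse_cigar,
    read_sam,
    sw_affine,
    write_sam,
)
from transgenemap.reference import (
    Assembly,
    Contig,
    GenomicInterval,
    TransgeneConstruct,
    build_combined_reference,
    encode_seq,
    revcomp,
)

_ALPH = bseq.NucleotideSequence.alphabet_unamb


def biotite_local_score(query: str, ref: str, scoring: ScoringScheme) -> int:
    """Independent optimal local alignment score (biotite DP)."""
    mat = np.full((4, 4), scoring.mismatch, dtype=np.int32)
    np.fill_diagonal(mat, scoring.match)
    m = balign.SubstitutionMatrix(_ALPH, _ALPH, mat)
    alns = balign.align_optimal(
        bseq.NucleotideSequence(query),
        bseq.NucleotideSequence(ref),
        m,
        gap_penalty=(scoring.gap_open, scoring.gap_extend),
        local=True,
    )
    return int(alns[0].score)


def _mutate(rng, s: str, subs=0, ins=0, dels=0) -> str:
    arr = list(s)
    for _ in range(subs):
        i = rng.integers(len(arr))
        arr[i] = "ACGT"[(("ACGT".index(arr[i])) + 1 + rng.integers(3)) % 4]
    for _ in range(dels):
        del arr[rng.integers(len(arr))]
    for _ in range(ins):
        arr.insert(int(rng.integers(len(arr))), "ACGT"[rng.integers(4)])
    return "".join(arr)


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ref_fixture(rng, host_len=20_000):
    host_seq = _rand_dna(rng, host_len)
    construct = TransgeneConstruct(
        _rand_dna(rng, 2000),
        {"promoter": GenomicInterval("tg", 1, 500)},
        "tg",
    )
    host = Assembly([Contig("chr1", host_seq)])
    ref = build_combined_reference(host, construct)
    return ref, build_index(ref, k=21)


class TestCigar:
    def test_parse_round_trip(self):
        assert parse_cigar("60M41S") == [("M", 60), ("S", 41)]
        assert parse_cigar("*") == []

    def test_parse_rejects_junk(self):
        with pytest.raises(AlignerError):
            parse_cigar("12X")


class TestSwAffineOracle:
    def test_matches_biotite_on_random_pairs(self, rng, scoring):
        """Local DP score identical to biotite's optimal local alignment."""
        for _ in range(30):
            q = _rand_dna(rng, int(rng.integers(15, 70)))
            r = _rand_dna(rng, int(rng.integers(15, 90)))
            s, cig, *_ = sw_affine(encode_seq(q), encode_seq(r), scoring, local=True)
            assert s == biotite_local_score(q, r, scoring)

    def test_matches_biotite_on_related_pairs(self, rng, scoring):
        for _ in range(25):
            r = _rand_dna(rng, int(rng.integers(60, 120)))
            q = _mutate(rng, r, subs=int(rng.integers(0, 4)),
                        ins=int(rng.integers(0, 2)), dels=int(rng.integers(0, 2)))
            s, *_ = sw_affine(encode_seq(q), encode_seq(r), scoring, local=True)
            assert s == biotite_local_score(q, r, scoring)

    def test_cigar_consistent_with_score(self, rng, scoring):
        """Re-scoring the traceback reproduces the DP score."""
        for _ in range(20):
            r = _rand_dna(rng, 80)
            q = _mutate(rng, r[10:70], subs=2, ins=1, dels=1)
            s, cigar, r0, q0, q1 = sw_affine(encode_seq(q), encode_seq(r), scoring, local=True)
            score, qi, ri = 0, q0, r0
            for op, n in cigar:
                if op == "M":
                    for _ in range(n):
                        score += scoring.match if q[qi] == r[ri] else scoring.mismatch
                        qi, ri = qi + 1, ri + 1
                elif op == "I":
                    score += scoring.gap_open + (n - 1) * scoring.gap_extend
                    qi += n
                else:
                    score += scoring.gap_open + (n - 1) * scoring.gap_extend
                    ri += n
            assert score == s and qi == q1

    def test_glocal_consumes_full_query(self, rng, scoring):
        r = _rand_dna(rng, 200)
        q = r[50:130]
        s, cigar, r0, q0, q1 = sw_affine(encode_seq(q), encode_seq(r), scoring, local=False)
        assert (q0, q1) == (0, len(q))
        assert s == len(q) * scoring.match
        assert r0 == 50


class TestSeedAligner:
    def test_exact_and_revcomp_reads(self, rng, scoring):
        ref, index = _ref_fixture(rng)
        seq = ref.host["chr1"].sequence
        for _ in range(15):
            p0 = int(rng.integers(0, len(seq) - 101))
            read = seq[p0 : p0 + 101]
            for strand, q in (("+", read), ("-", revcomp(read))):
                rec = align_end_to_end(q, index, scoring)
                assert (rec.contig, rec.pos, rec.strand) == ("chr1", p0 + 1, strand)
                assert rec.score == 101 * scoring.match
                assert rec.unique

    def test_local_score_equals_dp_oracle(self, rng, scoring):
        """Seed-and-extend local score equals the exhaustive DP optimum."""
        ref, index = _ref_fixture(rng, host_len=20_000)
        whole = ref.host["chr1"].sequence + ref.construct.sequence
        seq = ref.host["chr1"].sequence
        for i in range(12):
            p0 = int(rng.integers(0, len(seq) - 101))
            q = _mutate(rng, seq[p0 : p0 + 101],
                        subs=int(rng.integers(0, 3)),
                        ins=int(i % 3 == 1), dels=int(i % 3 == 2))
            rec = align_local(q, index, scoring)
            oracle = max(
                biotite_local_score(q, seq, scoring),
                biotite_local_score(q, revcomp(seq), scoring),
                biotite_local_score(q, ref.construct.sequence, scoring),
            )
            assert rec.is_mapped
            assert rec.score == oracle

    def test_chimeric_read_soft_clipped(self, rng, scoring):
        ref, index = _ref_fixture(rng)
        host_seq = ref.host["chr1"].sequence
        # pick an unambiguous junction: the next host base must differ from
        # the construct's first base, else the breakpoint itself is ambiguous
        p0 = 5000
        while host_seq[p0 + 60] == ref.construct.sequence[0]:
            p0 += 1
        q = host_seq[p0 : p0 + 60] + ref.construct.sequence[:41]
        rec = align_local(q, index, scoring)
        assert rec.contig == "chr1"
        assert rec.pos == p0 + 1 and rec.end == p0 + 60
        assert rec.right_clip == 41
        clip = align_local(q[60:], index, scoring)
        assert clip.contig == "tg" and clip.pos == 1

    def test_duplicated_region_not_unique(self, rng, scoring):
        seq = _rand_dna(rng, 6000)
        dup = seq[1000:1400]
        seq = seq + dup  # second, identical copy at the end
        host = Assembly([Contig("chr1", seq)])
        construct = TransgeneConstruct(_rand_dna(rng, 1000), {}, "tg")
        index = build_index(build_combined_reference(host, construct), k=21)
        read = dup[100:201]
        rec = align_end_to_end(read, index)
        assert rec.is_mapped and not rec.unique
        # ties break to the leftmost placement
        assert rec.pos == 1101

    def test_garbage_read_unmapped(self, rng, scoring):
        ref, index = _ref_fixture(rng)
        rec = align_end_to_end("ACGT" * 25 + "A", index, scoring)
        assert not rec.is_mapped

    def test_align_pairs_proper_flag(self, rng, scoring):
        ref, index = _ref_fixture(rng)
        seq = ref.host["chr1"].sequence
        frag = seq[3000:3350]
        pairs = [("p0", frag[:101], revcomp(frag[-101:]))]
        recs = align_pairs(pairs, index, scoring, InsertModel(350, 35))
        assert len(recs) == 2
        assert all(r.proper_pair for r in recs)
        # distant mates are not proper
        recs = align_pairs([("p1", seq[100:201], revcomp(seq[9000:9101]))], index, scoring)
        assert not any(r.proper_pair for r in recs)

    def test_bad_mode_rejected(self, rng):
        ref, index = _ref_fixture(rng)
        with pytest.raises(AlignerError):
            align_pairs([("a", "ACGT", "ACGT")], index, mode="banana")


class TestSamIO:
    def test_round_trip(self, tmp_path, rng, scoring):
        ref, index = _ref_fixture(rng)
        seq = ref.host["chr1"].sequence
        pairs = []
        for i in range(5):
            p0 = int(rng.integers(0, len(seq) - 400))
            frag = seq[p0 : p0 + 350]
            pairs.append((f"p{i}", frag[:101], revcomp(frag[-101:])))
        recs = align_pairs(pairs, index, scoring, InsertModel())
        path = write_sam(recs, ref, tmp_path / "x.sam")
        back = read_sam(path)
        assert len(back) == len(recs)
        for a, b in zip(sorted(recs, key=lambda r: (r.query_name, not r.is_read1)),
                        sorted(back, key=lambda r: (r.query_name, not r.is_read1))):
            assert (a.contig, a.pos, a.strand, a.cigar, a.unique) == (
                b.contig, b.pos, b.strand, b.cigar, b.unique)
            assert a.seq == b.seq
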