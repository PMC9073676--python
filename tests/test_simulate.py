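"""Simulator: event splicing, coordinate maps, read generation, truth SAM."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from Bio import SeqIO

from transgenemap.junctions import classify_target_site
from transgenemap.reference import Assembly, Contig, GenomicInterval, revcomp
from transgenemap.simulate import (
    I_SCEI_SITE,
    InsertionEvent,
    ReadSimParams,
    SimulationError,
    apply_insertion_events,
    default_construct,
    emit_truth_sam,
    make_event,
    make_wildtype_haplotype,
    paper_scenario,
    promoter_equivalence,
    simulate_host_genome,
    simulate_reads,
    write_fastq_pair,
)


def _host(n=4000, seed=5):
    return simulate_host_genome(n, gc=0.4, seed=seed)


def _splice(seq: str, L: int, R: int, payload: str) -> str:
    """Independent oracle for the splice semantics of an insertion event."""
    return seq[:L] + payload + seq[R - 1 :]


class TestInsertionEvents:
    def test_blunt_deletion_duplication_strings(self):
        host = _host()
        seq = host["chr1"].sequence
        payload = "ACGTACGTACGT"
        for L, R in [(1000, 1001), (1000, 1012), (1000, 990)]:
            ev = InsertionEvent("chr1", L, R, payload)
            hap = apply_insertion_events(host, [ev])
            assert hap.assembly["chr1"].sequence == _splice(seq, L, R, payload)

    def test_classifier_generator_identity(self):
        """classify_target_site inverts the generator over offsets [-50, 50]."""
        host = _host()
        seq = host["chr1"].sequence
        payload = "TTTTGGGGCCCCAAAA"
        L = 2000
        for off in range(-50, 51):
            R = L + 1 + off
            ev = InsertionEvent("chr1", L, R, payload)
            hap = apply_insertion_events(host, [ev])
            assert hap.assembly["chr1"].sequence == _splice(seq, L, R, payload)
            lesion = classify_target_site(L, R)
            if off == 0:
                assert lesion.kind == "blunt" and lesion.length == 0
            elif off > 0:
                assert lesion.kind == "deletion"
                assert lesion.length == off
                assert (lesion.start, lesion.end) == (L + 1, R - 1)
                # the haplotype lost exactly `off` host bases
                assert len(hap.assembly["chr1"].sequence) == len(seq) + len(payload) - off
            else:
                assert lesion.kind == "duplication"
                assert lesion.length == -off  # L - R + 1 with R = L + 1 + off
                assert (lesion.start, lesion.end) == (R, L)
                dup = seq[R - 1 : L]
                # the duplicated run flanks the payload on both sides
                allele = hap.assembly["chr1"].sequence
                assert allele[L - len(dup) : L] == dup
                assert allele[L + len(payload) : L + len(payload) + len(dup)] == dup

    def test_segment_map_is_faithful(self):
        host = _host()
        construct = default_construct()
        ev = make_event("chr1", 1500, 1495, construct, 2, ("+", "-"))
        hap = apply_insertion_events(host, [ev], construct=construct)
        allele = hap.assembly["chr1"].sequence
        covered = 0
        for seg in hap.segments["chr1"]:
            piece = allele[seg.allele_start0 : seg.allele_end0]
            if seg.ref_contig == "chr1":
                ref_piece = host["chr1"].sequence[seg.ref_start0 : seg.ref_start0 + seg.length]
            else:
                ref_piece = construct.sequence[seg.ref_start0 : seg.ref_start0 + seg.length]
            if seg.strand == "-":
                ref_piece = revcomp(ref_piece)
            assert piece == ref_piece
            covered += seg.length
        assert covered == len(allele)

    def test_overlapping_events_rejected(self):
        host = _host()
        evs = [InsertionEvent("chr1", 100, 101, "AA"), InsertionEvent("chr1", 100, 101, "CC")]
        with pytest.raises(SimulationError):
            apply_insertion_events(host, evs)

    def test_event_validation(self):
        with pytest.raises(SimulationError):
            InsertionEvent("chr1", 0, 5, "A")
        with pytest.raises(SimulationError):
            InsertionEvent("chr1", 5, 6, "A", copies=2, orientations=("+",))

    def test_event_outside_contig(self):
        host = _host(1000)
        with pytest.raises(SimulationError):
            apply_insertion_events(host, [InsertionEvent("chr1", 5000, 5001, "A")])


class TestHostGenome:
    def test_gc_near_target(self):
        host = simulate_host_genome(100_000, gc=0.4, seed=3)
        seq = host["chr1"].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4) < 0.01

    def test_plant_and_bounds(self):
        host = simulate_host_genome(100, plant=[(11, "TTTT")], seed=0)
        assert host["chr1"].sequence[10:14] == "TTTT"
        with pytest.raises(SimulationError):
            simulate_host_genome(100, plant=[(99, "AAAA")])

    def test_deterministic(self):
        a = simulate_host_genome(500, seed=9)["chr1"].sequence
        b = simulate_host_genome(500, seed=9)["chr1"].sequence
        assert a == b


class TestReadSimulation:
    def test_pair_count_formula(self):
        host = _host(50_000)
        wt = make_wildtype_haplotype(host)
        params = ReadSimParams(depth=10.0, seed=1)
        reads = simulate_reads([wt, wt], params)
        # depth * (sum of allele lengths)/2 / (2 * read_length)
        expected = int(round(10.0 * 50_000 / (2 * 101)))
        assert reads.n_pairs == expected

    def test_error_free_reads_match_haplotype(self):
        host = _host(30_000)
        wt = make_wildtype_haplotype(host)
        params = ReadSimParams(depth=4.0, error_rate=0.0, seed=2)
        reads = simulate_reads([wt], params)
        seq = host["chr1"].sequence
        for i in range(min(reads.n_pairs, 200)):
            for s0, neg, read in (
                (int(reads.r1_start0[i]), bool(reads.r1_strand[i]), reads.r1_seq(i)),
                (int(reads.r2_start0[i]), bool(reads.r2_strand[i]), reads.r2_seq(i)),
            ):
                truth = seq[s0 : s0 + 101]
                assert read == (revcomp(truth) if neg else truth)

    def test_error_rate_calibrated(self):
        host = _host(30_000)
        wt = make_wildtype_haplotype(host)
        params = ReadSimParams(depth=6.0, error_rate=0.01, seed=3)
        reads = simulate_reads([wt], params)
        seq = host["chr1"].sequence
        mism = tot = 0
        for i in range(reads.n_pairs):
            s0, neg = int(reads.r1_start0[i]), bool(reads.r1_strand[i])
            truth = seq[s0 : s0 + 101]
            read = reads.r1_seq(i)
            if neg:
                read = revcomp(read)
            mism += sum(a != b for a, b in zip(read, truth))
            tot += 101
        rate = mism / tot
        assert 0.005 < rate < 0.02

    def test_fastq_round_trip(self, tmp_path):
        host = _host(20_000)
        wt = make_wildtype_haplotype(host)
        reads = simulate_reads([wt], ReadSimParams(depth=2.0, seed=4))
        p1, p2 = write_fastq_pair(reads, tmp_path / "r1.fq", tmp_path / "r2.fq")
        rec1 = list(SeqIO.parse(str(p1), "fastq"))
        rec2 = list(SeqIO.parse(str(p2), "fastq"))
        assert len(rec1) == len(rec2) == reads.n_pairs
        assert str(rec1[0].seq) == reads.r1_seq(0)
        assert all(len(r.seq) == 101 for r in rec1[:20])


class TestTruthSam:
    def test_parses_and_covers(self, tmp_path, scenario_small):
        sc = scenario_small
        sam = emit_truth_sam(
            sc.reads, sc.haplotypes, sc.reference, tmp_path / "t.sam",
            promoter_equiv=promoter_equivalence(sc),
        )
        with pysam.AlignmentFile(str(sam), "r") as fh:
            recs = list(fh)
        assert len(recs) == 2 * sc.reads.n_pairs
        assert all(not r.is_unmapped for r in recs)
        # per-base depth over a quiet host window approximates the target depth
        depth = np.zeros(sc.reference.host.total_length + 1)
        for r in recs:
            if r.reference_name == "chr1":
                depth[r.reference_start : r.reference_end] += 1
        window = depth[2000:10000]
        assert abs(window.mean() - 20.0) < 2.0


class TestPaperScenario:
    def test_geometry_and_truth(self, scenario_small):
        sc = scenario_small
        (L1, R1), (L2, R2) = sc.truth_boundaries
        assert (R1 - L1, L2 - R2) == (12, 14)
        assert classify_target_site(L1, R1).length == 11
        assert classify_target_site(L2, R2).length == 15
        assert min(L2, R2) - max(L1, R1) == 108
        assert sc.expected_copies == {"promoter": 6, "egfp": 6, "vector": 6}

    def test_planted_motifs_present(self, scenario_small):
        sc = scenario_small
        host = sc.reference.host
        assert host.fetch(sc.planted_motifs["recognition_site_remnant"]) == I_SCEI_SITE[:6]
        assert host.fetch(sc.planted_motifs["overhang"]) == "ATAA"
        f1 = host.fetch(sc.planted_motifs["flank_homology_I1"])
        f2 = host.fetch(sc.planted_motifs["flank_homology_I2"])
        assert f1 == f2 and len(f1) == 8

    def test_junction_guard_bases(self, scenario_small):
        """The host base just inside each lesion differs from the construct
        terminal base, so breakpoints are identifiable at 1-bp resolution."""
        sc = scenario_small
        seq = sc.reference.host["chr1"].sequence
        first, last = sc.construct.sequence[0], sc.construct.sequence[-1]
        for L, R in sc.truth_boundaries:
            assert seq[L] != first  # base at L+1 (0-based L)
            assert seq[R - 2] != last  # base at R-1

    def test_endogenous_promoter_planted(self, scenario_small):
        sc = scenario_small
        planted = sc.reference.host.fetch(sc.promoter_host_interval)
        assert planted == sc.construct.feature_seq("promoter")

    def test_host_too_short(self):
        with pytest.raises(SimulationError):
            paper_scenario(host_length=10_000)

    def test_truth_json_schema(self, scenario_small):
        t = scenario_small.truth_json()
        assert len(t["events"]) == 2
        assert sum(e["copies"] for e in t["events"]) == 6
        assert t["n_pairs"] == scenario_small.reads.n_pairs


class TestDefaultConstruct:
    def test_flanked_by_recognition_sites(self):
        c = default_construct()
        assert len(c) == 8000
        assert c.sequence[:18] == I_SCEI_SITE
        assert c.sequence[-18:] == revcomp(I_SCEI_SITE)
        assert set(c.features) >= {"promoter", "egfp", "vector"}

    def test_deterministic(self):
        assert default_construct().sequence == default_construct().sequence
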