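"""Junction calling: lesion classification, clustering, pairing, PCR check."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transgenemap.junctions import (
    Boundary,
    IntegrationSite,
    JunctionError,
    SplitRead,
    classify_target_site,
    cluster_boundaries,
    in_silico_pcr,
    pair_boundaries_into_sites,
    reconstruct_allele,
    site_distance,
    sites_report,
    sites_to_bed,
)
from transgenemap.reference import GenomicInterval, revcomp

# boundary coordinates of the two integration loci as printed for the
# snai2:eGFP line on chromosome 1
I1_L, I1_R = 86_757_200, 86_757_212
I2_L, I2_R = 86_757_334, 86_757_320


def _boundary(pos, side, term="start", orient="+", contig="chr1", splits=5, pairs=2):
    return Boundary(contig, pos, side, term, orient, splits, pairs)


def _site(left_pos, right_pos, contig="chr1"):
    lb = _boundary(left_pos, "left", "start", "+", contig)
    rb = _boundary(right_pos, "right", "end", "+", contig)
    return IntegrationSite(lb, rb, classify_target_site(left_pos, right_pos))


class TestClassifyTargetSite:
    def test_printed_deletion(self):
        lesion = classify_target_site(I1_L, I1_R)
        assert lesion.kind == "deletion"
        assert lesion.length == 11
        assert (lesion.start, lesion.end) == (86_757_201, 86_757_211)

    def test_printed_duplication(self):
        lesion = classify_target_site(I2_L, I2_R)
        assert lesion.kind == "duplication"
        assert lesion.length == 15
        assert (lesion.start, lesion.end) == (86_757_320, 86_757_334)

    def test_blunt(self):
        lesion = classify_target_site(100, 101)
        assert lesion.kind == "blunt" and lesion.length == 0

    def test_invalid(self):
        with pytest.raises(JunctionError):
            classify_target_site(0, 5)

    @given(st.integers(1, 10**8), st.integers(1, 10**8))
    def test_invariants(self, L, R):
        lesion = classify_target_site(L, R)
        if lesion.kind == "blunt":
            assert R == L + 1 and lesion.length == 0
        elif lesion.kind == "deletion":
            assert lesion.length == R - L - 1 > 0
            assert (lesion.start, lesion.end) == (L + 1, R - 1)
        else:
            assert lesion.length == L - R + 1 > 0
            assert (lesion.start, lesion.end) == (R, L)


class TestSiteDistance:
    def test_printed_coordinates_give_108(self):
        assert site_distance(_site(I1_L, I1_R), _site(I2_L, I2_R)) == 108

    def test_symmetric(self):
        a, b = _site(I1_L, I1_R), _site(I2_L, I2_R)
        assert site_distance(a, b) == site_distance(b, a)

    def test_identical_sites_zero(self):
        assert site_distance(_site(1000, 1012), _site(1000, 1012)) == 0

    def test_overlapping_clamped_to_zero(self):
        assert site_distance(_site(1000, 1012), _site(1005, 1017)) == 0


def _split(pos, side="left", coord=1, orient="+", rid="s"):
    return SplitRead(
        read_id=rid,
        anchor_side="host",
        anchor=GenomicInterval("chr1", max(1, pos - 80), pos),
        clip_side="right",
        clip_length=30,
        remap=GenomicInterval("tg", 1, 30),
        host_pos=pos,
        host_contig="chr1",
        boundary_side=side,
        construct_coord=coord,
        construct_orient=orient,
    )


class TestClusterBoundaries:
    def test_modal_position_and_shift_range(self):
        splits = [_split(1000, rid=f"a{i}") for i in range(3)] + [_split(1002, rid="b")]
        kept, dropped = cluster_boundaries(splits, min_support=3)
        assert len(kept) == 1 and dropped.empty
        b = kept[0]
        assert b.pos == 1000 and b.split_support == 4
        assert b.shift_range == (1000, 1002)

    def test_window_separates_clusters(self):
        splits = [_split(1000, rid=f"a{i}") for i in range(3)]
        splits += [_split(1050, rid=f"b{i}") for i in range(3)]
        kept, _ = cluster_boundaries(splits, window=10, min_support=3)
        assert [b.pos for b in kept] == [1000, 1050]

    def test_support_rule(self):
        # two splits, no pairs: dropped
        kept, dropped = cluster_boundaries([_split(1000, rid="a"), _split(1000, rid="b")])
        assert not kept and len(dropped) == 1
        assert dropped.loc[0, "split_support"] == 2

    def test_orientation_separates_groups(self):
        splits = [_split(1000, orient="+", rid=f"a{i}") for i in range(3)]
        splits += [_split(1000, orient="-", rid=f"b{i}") for i in range(3)]
        kept, _ = cluster_boundaries(splits, min_support=3)
        assert len(kept) == 2


class TestPairing:
    def test_compatibility(self):
        # same orientation joins opposite termini
        lb = _boundary(1000, "left", "start", "+")
        rb = _boundary(1012, "right", "end", "+")
        sites, half = pair_boundaries_into_sites([lb, rb])
        assert len(sites) == 1 and not half
        # same orientation and same terminus cannot close a site
        rb_bad = _boundary(1012, "right", "start", "+")
        sites, half = pair_boundaries_into_sites([lb, rb_bad])
        assert not sites and len(half) == 2
        # opposite orientation joins equal termini (inverted concatemer)
        rb_inv = _boundary(1012, "right", "start", "-")
        sites, half = pair_boundaries_into_sites([lb, rb_inv])
        assert len(sites) == 1

    def test_internal_terminus_never_pairs(self):
        lb = _boundary(1000, "left", "internal", "+")
        rb = _boundary(1012, "right", "end", "+")
        sites, half = pair_boundaries_into_sites([lb, rb])
        assert not sites and len(half) == 2

    def test_assignment_minimises_distance(self):
        lbs = [_boundary(1000, "left"), _boundary(5000, "left")]
        rbs = [_boundary(5012, "right", "end"), _boundary(1012, "right", "end")]
        sites, half = pair_boundaries_into_sites(lbs + rbs)
        assert not half
        assert sorted(s.boundary_positions for s in sites) == [(1000, 1012), (5000, 5012)]

    def test_max_span(self):
        lb, rb = _boundary(1000, "left"), _boundary(90_000, "right", "end")
        sites, half = pair_boundaries_into_sites([lb, rb], max_span=10_000)
        assert not sites and len(half) == 2


class TestReports:
    def test_sites_report_and_bed(self):
        sites = [_site(I1_L, I1_R), _site(I2_L, I2_R)]
        rep = sites_report(sites)
        assert [s["name"] for s in rep["sites"]] == ["I1", "I2"]
        assert rep["sites"][0]["lesion"]["length"] == 11
        bed = sites_to_bed(sites)
        line1 = bed.splitlines()[0].split("\t")
        assert line1[:3] == ["chr1", str(I1_L - 1), str(I1_R)]


class TestReconstructAllele:
    def test_round_trip_with_generator(self, scenario_small):
        """Reconstruction from truth-equivalent sites reproduces the
        simulated transgenic haplotype exactly."""
        sc = scenario_small
        sites = [_site(L, R) for L, R in sc.truth_boundaries]
        allele = reconstruct_allele(
            sites, sc.reference.host, sc.construct,
            copies_per_site=[e.copies for e in sc.events],
            orientations=[list(e.orientations) for e in sc.events],
        )
        assert allele == sc.haplotypes[1].assembly["chr1"].sequence


class TestInSilicoPcr:
    def test_amplicon_found_both_role_orders(self):
        rng = np.random.default_rng(7)
        template = "".join(rng.choice(list("ACGT"), size=2000))
        fwd = template[100:120]
        rev = revcomp(template[380:400])
        for a, b in ((fwd, rev), (rev, fwd)):
            amps = in_silico_pcr(template, a, b)
            assert len(amps) == 1
            assert (amps[0].start, amps[0].end, amps[0].length) == (101, 400, 300)
            assert amps[0].sequence == template[100:400]

    def test_max_len(self):
        rng = np.random.default_rng(8)
        template = "".join(rng.choice(list("ACGT"), size=9000))
        fwd = template[0:20]
        rev = revcomp(template[8000:8020])
        assert in_silico_pcr(template, fwd, rev, max_len=5000) == []


class TestPipelineJunctions:
    def test_sites_recovered_at_truth(self, pipeline_200k):
        result, _ = pipeline_200k
        truth = result.scenario.truth_boundaries
        called = [s.boundary_positions for s in result.sites]
        assert called == truth
        assert [s.lesion.kind for s in result.sites] == ["deletion", "duplication"]
        assert [s.lesion.length for s in result.sites] == [11, 15]
        assert result.report["site_distance_bp"] == 108
        assert not result.half_sites

    def test_support_counts_reported(self, pipeline_200k):
        result, _ = pipeline_200k
        for site in result.sites:
            assert site.left.split_support >= 1 and site.right.split_support >= 1
            assert site.total_support >= 6

    def test_concatemer_head_to_tail(self, pipeline_200k):
        result, _ = pipeline_200k
        assert result.concatemer_junctions
        top = result.concatemer_junctions[0]
        assert top.orientation == "head-to-tail"
        assert set(top.joined) == {"start", "end"}
        # copy-copy junction joins the construct's last base to its first
        clen = len(result.scenario.construct)
        assert sorted(top.breakpoints) == [1, clen]
        assert top.split_support >= 5
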