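import numpy as np
import pytest

from cnvpath.data_io import CnvRecord, GeneModel
from cnvpath.gene_areas import (build_gene_areas, build_pseudo_transcriptome,
                                pair_by_flank, pair_overlaps, pair_placements,
                                pair_truncated, truncate_cnvs)
from oracles import base_assignment, pair_brute_force


def gm(gid, start, end, chrom="chr1"):
    return GeneModel(gid, chrom, start, end)


def cnv(cid, start, end, chrom="chr1"):
    return CnvRecord(cid, chrom, start, end)


class TestBuildGeneAreas:
    def test_clipped_at_chromosome_origin(self):
        (a,) = build_gene_areas([gm("G1", 1000, 2000)], flank=10_000)
        assert (a.start, a.end) == (0, 12_000)

    def test_non_overlapping_areas_untouched(self):
        areas = build_gene_areas(
            [gm("A", 0, 100), gm("B", 10_000, 10_100)], flank=100)
        assert [(a.start, a.end) for a in areas] == [(0, 200), (9_900, 10_200)]

    def test_overlap_split_at_body_midpoint(self):
        # bodies [0,1000) and [1500,2500), flank 1000: contested zone is cut
        # at 1250, the midpoint between body end 1000 and body start 1500
        areas = build_gene_areas(
            [gm("A", 0, 1000), gm("B", 1500, 2500)], flank=1000)
        assert [(a.start, a.end) for a in areas] == [(0, 1250), (1250, 3500)]

    def test_areas_always_disjoint_and_sorted(self):
        rng = np.random.default_rng(5)
        genes = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(100, 5000))
            length = int(rng.integers(200, 4000))
            genes.append(gm(f"G{i}", pos, pos + length))
            pos += length
        areas = build_gene_areas(genes, flank=2000)
        for left, right in zip(areas, areas[1:]):
            assert left.end <= right.start
            assert left.start < left.end


class TestPseudoTranscriptome:
    def test_offsets_and_total_length(self):
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 0, 100), gm("B", 10_000, 10_100)], flank=100))
        assert pt.length("chr1") == 500
        starts, _ = pt.area_bounds("chr1")
        assert list(starts) == [0, 200]

    def test_known_mapping(self):
        # genomic base 9950 lies in the second area [9900,10200) at offset 200
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 0, 100), gm("B", 10_000, 10_100)], flank=100))
        assert pt.to_concat("chr1", 9950) == 250
        assert pt.to_genomic("chr1", 250) == 9950

    def test_empty_chromosome(self):
        pt = build_pseudo_transcriptome([])
        assert pt.length("chrX") == 0

    def test_mapping_is_bijective_on_random_bases(self):
        rng = np.random.default_rng(0)
        genes = [gm(f"G{i}", 20_000 * i, 20_000 * i + int(rng.integers(500, 8000)))
                 for i in range(50)]
        pt = build_pseudo_transcriptome(build_gene_areas(genes, flank=3000))
        L = pt.length("chr1")
        for c in rng.integers(0, L, size=10_000):
            g = pt.to_genomic("chr1", int(c))
            assert pt.to_concat("chr1", g) == int(c)

    def test_overlapping_areas_rejected(self):
        from cnvpath.gene_areas import GeneArea
        with pytest.raises(ValueError, match="overlapping"):
            build_pseudo_transcriptome([GeneArea("A", "chr1", 0, 100),
                                        GeneArea("B", "chr1", 50, 150)])


class TestTruncateCnvs:
    @pytest.fixture()
    def pt(self):
        return build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 100, 300), gm("B", 600, 900)], flank=0))

    def test_partial_overlap_clipped(self, pt):
        (t,) = truncate_cnvs([cnv("c", 50, 150)], pt)
        assert t.segments == ((100, 150),)
        assert t.total_size == 50

    def test_outside_all_areas_excluded(self, pt):
        assert truncate_cnvs([cnv("c", 400, 500)], pt) == []

    def test_spanning_two_areas_sums_segments(self, pt):
        (t,) = truncate_cnvs([cnv("c", 200, 700)], pt)
        assert t.segments == ((200, 300), (600, 700))
        assert t.total_size == 200

    def test_total_size_bounded_by_original(self, pt):
        cnvs = [cnv(f"c{i}", i * 37, i * 37 + 120) for i in range(20)]
        total = sum(t.total_size for t in truncate_cnvs(cnvs, pt))
        assert total <= sum(c.length for c in cnvs)


class TestPairingRules:
    def test_majority_area_wins(self):
        # 60% of the CNV in A's area, 40% in B's
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 0, 1000), gm("B", 1000, 2000)], flank=0))
        pairs = pair_overlaps([cnv("c", 400, 1400)], pt)
        assert [(p.cnv_id, p.gene_id) for p in pairs] == [("c", "A")]

    def test_area_entirely_inside_cnv_paired(self):
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("G", 200, 400), gm("H", 400, 2000)], flank=0))
        pairs = pair_overlaps([cnv("c", 0, 1000)], pt)
        assert {p.gene_id for p in pairs} == {"G", "H"}  # G by R1, H by R3

    def test_exact_half_split_goes_to_lower_coordinate(self):
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 0, 1000), gm("B", 1000, 2000)], flank=0))
        pairs = pair_overlaps([cnv("c", 500, 1500)], pt)
        assert [(p.cnv_id, p.gene_id) for p in pairs] == [("c", "A")]

    def test_agrees_with_base_by_base_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            genes = []
            pos = 0
            for i in range(20):
                pos += int(rng.integers(50, 3000))
                end = pos + int(rng.integers(100, 4000))
                genes.append(gm(f"G{i}", pos, end))
                pos = end
            areas = build_gene_areas(genes, flank=int(rng.integers(0, 1500)))
            pt = build_pseudo_transcriptome(areas)
            area_list = [(a.gene_id, a.start, a.end) for a in areas]
            cnvs = []
            for j in range(50):
                s = int(rng.integers(0, pos))
                cnvs.append(cnv(f"c{j}", s, s + int(rng.integers(50, 5000))))
            got = {}
            for p in pair_overlaps(cnvs, pt):
                got.setdefault(p.cnv_id, set()).add(p.gene_id)
            assignment = base_assignment(area_list, pos + 10_000)
            for c in cnvs:
                expect = pair_brute_force(c.start, c.end, area_list, assignment)
                assert got.get(c.cnv_id, set()) == expect, c


class TestPairPlacements:
    def test_matches_truncated_pairing_on_contiguous_block(self):
        pt = build_pseudo_transcriptome(build_gene_areas(
            [gm("A", 0, 1000), gm("B", 1000, 2000), gm("C", 2000, 2300)],
            flank=0))
        pairs = pair_placements(["x"], "chr1", np.array([400]),
                                np.array([1900]), pt)
        assert {p.gene_id for p in pairs} == {"B", "C"}


class TestPairByFlank:
    def test_distal_cnv_needs_large_flank(self):
        genes = [gm("G", 1_000_000, 1_165_000)]
        c = cnv("c", 938_000, 942_000)  # 58 kb upstream of the gene
        assert pair_by_flank([c], genes, 1_000_000)
        assert not pair_by_flank([c], genes, 10_000)

    def test_cnv_inside_gene_pairs_at_any_flank(self):
        genes = [gm("G", 1000, 50_000)]
        for flank in (0, 10_000, 1_000_000):
            assert pair_by_flank([cnv("c", 2000, 2500)], genes, flank)
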