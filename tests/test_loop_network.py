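"""Loop filtering, anchor classification, ATAC gating, naming, gene linking."""
import numpy as np
import pytest

from heptadnet.core_intervals import GenomicInterval, GeneModel, IntervalSet, PeakCollection
from heptadnet.loop_network import (
    Loop,
    build_gene_network,
    classify_anchors,
    filter_loops,
    gate_by_atac,
    link_regions_to_genes,
    name_element,
    read_bedpe,
    write_bedpe,
)


def mk_loop(chrom, s1, e1, s2, e2, q):
    return Loop(GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2), q)


@pytest.fixture
def gene_plus():
    return GeneModel.from_body("g", "GENE", GenomicInterval("chr1", 1_000_000, 1_020_000, "+"), "+")


class TestFilter:
    def test_boundary_inclusive(self):
        kept = filter_loops([mk_loop("c", 0, 10, 50, 60, 0.01)], 0.01)
        assert len(kept) == 1
        assert filter_loops([mk_loop("c", 0, 10, 50, 60, 0.011)], 0.01) == []

    def test_manual_enumeration(self, rng):
        qs = rng.uniform(0, 0.05, size=20)
        loops = [mk_loop("c", i * 100, i * 100 + 10, 5000, 5010, q) for i, q in enumerate(qs)]
        kept = filter_loops(loops, 0.01)
        assert [l.q_value for l in kept] == [q for q in qs if q <= 0.01]

    def test_q_value_required(self):
        with pytest.raises(ValueError):
            mk_loop("c", 0, 10, 50, 60, float("nan"))

    def test_bedpe_roundtrip(self, tmp_path):
        loops = [mk_loop("c1", 0, 5000, 90_000, 95_000, 0.004),
                 mk_loop("c2", 100, 5100, 50_000, 55_000, 0.3)]
        p = tmp_path / "loops.bedpe"
        write_bedpe(loops, p)
        back = read_bedpe(p, q_col=8)
        assert [l.q_value for l in back] == pytest.approx([0.004, 0.3])
        assert back[0].anchor_b.start == 90_000


class TestClassifyAnchors:
    def test_tss_anchor_is_promoter(self, gene_plus):
        lp = mk_loop("chr1", 995_000, 1_005_000, 1_500_000, 1_505_000, 0.001)
        ann = classify_anchors([lp], [gene_plus])[0]
        assert ann.loop_class == "P-E" and ann.distal == "b"
        assert ann.genes_a == ("GENE",)

    def test_far_anchors_are_ee(self, gene_plus):
        lp = mk_loop("chr1", 3_000_000, 3_005_000, 5_000_000, 5_005_000, 0.001)
        assert classify_anchors([lp], [gene_plus])[0].loop_class == "E-E"

    def test_hand_derived_table(self, toy_genes):
        # GENE1 TSS=100000(+), GENE2 TSS=499999(-), GENE3 chr2 TSS=200000(+)
        loops = [
            mk_loop("chr1", 95_000, 101_000, 495_000, 505_000, 0.001),  # P-P
            mk_loop("chr1", 95_000, 101_000, 700_000, 705_000, 0.001),  # P-E
            mk_loop("chr1", 700_000, 705_000, 800_000, 805_000, 0.001),  # E-E
            mk_loop("chr2", 195_000, 201_000, 300_000, 305_000, 0.001),  # P-E
        ]
        classes = [a.loop_class for a in classify_anchors(loops, toy_genes)]
        assert classes == ["P-P", "P-E", "E-E", "P-E"]

    def test_empty_genes_rejected(self):
        with pytest.raises(ValueError):
            classify_anchors([], [])


class TestGate:
    def test_gating(self, gene_plus):
        with_atac = mk_loop("chr1", 995_000, 1_005_000, 1_500_000, 1_505_000, 0.001)
        without = mk_loop("chr1", 995_000, 1_005_000, 1_700_000, 1_705_000, 0.001)
        loops = [with_atac, without]
        anns = classify_anchors(loops, [gene_plus])
        atac = IntervalSet(["chr1"], [1_501_000], [1_501_600])
        kept = gate_by_atac(loops, anns, atac)
        assert kept == [with_atac]

    def test_containment_chain(self, gene_plus, rng):
        loops = [
            mk_loop("chr1", int(s), int(s) + 5_000, int(t), int(t) + 5_000, float(q))
            for s, t, q in zip(
                rng.integers(0, 2_000_000, 30),
                rng.integers(0, 2_000_000, 30),
                rng.uniform(0, 0.2, 30),
            )
        ]
        sig = filter_loops(loops, 0.01)
        anns = classify_anchors(sig, [gene_plus])
        pe = [l for l, a in zip(sig, anns) if a.loop_class == "P-E"]
        atac = IntervalSet(["chr1"], [0], [2_010_000])
        gated = gate_by_atac(sig, anns, atac)
        assert set(map(id, gated)) <= set(map(id, pe)) <= set(map(id, sig))


class TestNaming:
    def test_offset_arithmetic(self, gene_plus):
        el = GenomicInterval("chr1", 1_084_000, 1_086_000)  # midpoint 1,085,000
        assert name_element(el, gene_plus) == "GENE+85"

    def test_strand_flip_negates(self):
        minus = GeneModel.from_body(
            "g", "GENE", GenomicInterval("chr1", 980_000, 1_000_001, "-"), "-"
        )
        el = GenomicInterval("chr1", 1_084_000, 1_086_000)
        assert name_element(el, minus) == "GENE-85"

    def test_zero_offset(self, gene_plus):
        el = GenomicInterval("chr1", 999_900, 1_000_100)
        assert name_element(el, gene_plus) == "GENE+0"
        assert name_element(el, gene_plus, sub_kb=True) == "GENE+0.0"

    def test_sub_kb_rendering(self, gene_plus):
        el = GenomicInterval("chr1", 1_000_400, 1_000_600)  # +500 bp
        assert name_element(el, gene_plus, sub_kb=True) == "GENE+0.5"


class TestLinking:
    def test_direct_and_indirect(self, gene_plus):
        regions = IntervalSet(
            ["chr1", "chr1", "chr1"],
            [995_000, 1_500_500, 2_000_000],
            [995_600, 1_501_100, 2_000_600],
        )
        loops = [mk_loop("chr1", 998_000, 1_003_000, 1_498_000, 1_503_000, 0.001)]
        table = link_regions_to_genes(regions, [gene_plus], loops)
        by_region = table.set_index("region_index")
        assert by_region.loc[0, "link_type"] == "direct"
        assert by_region.loc[1, "link_type"] == "indirect"
        assert by_region.loc[2, "link_type"] == "unlinked"

    def test_hand_derived_mapping(self, toy_genes):
        # 4 regions: promoter of GENE1; looped to GENE2; unlinked; chr2 promoter
        regions = IntervalSet(
            ["chr1", "chr1", "chr1", "chr2"],
            [95_000, 700_100, 850_000, 198_000],
            [95_500, 700_700, 850_500, 198_500],
        )
        loops = [mk_loop("chr1", 698_000, 703_000, 495_000, 502_000, 0.002)]
        table = link_regions_to_genes(regions, toy_genes, loops)
        got = {
            (int(r.region_index), r.gene): r.link_type
            for r in table.itertuples() if r.link_type != "unlinked"
        }
        assert got == {
            (0, "GENE1"): "direct",
            (1, "GENE2"): "indirect",
            (3, "GENE3"): "direct",
        }
        assert (table["link_type"] == "unlinked").sum() == 1


class TestGeneNetwork:
    def test_no_loops_promoter_only(self, toy_genes):
        atac = IntervalSet(["chr1"], [0], [1_000])
        net = build_gene_network(
            "GENE1", toy_genes, {"X": []}, {"X": []}, {"X": atac}
        )
        assert len(net.elements) == 1 and net.elements[0].kind == "promoter"

    def test_unknown_gene_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            build_gene_network("NOPE", toy_genes, {}, {}, {})

    def test_planted_enhancers_counted(self, toy_genes):
        # three gated loops to GENE1 in cell "MEP" only
        loops_mep = [
            mk_loop("chr1", 98_000, 103_000, 200_000 + i * 50_000, 205_000 + i * 50_000, 0.001)
            for i in range(3)
        ]
        atac = IntervalSet(
            ["chr1"] * 3, [201_000, 251_000, 301_000], [201_600, 251_600, 301_600]
        )
        peaks = [
            PeakCollection(
                f, "MEP",
                IntervalSet(["chr1"] * 3, [201_100, 251_100, 301_100], [201_500, 251_500, 301_500]),
            )
            for f in ("FLI1", "ERG")
        ]
        net = build_gene_network(
            "GENE1", toy_genes,
            {"MEP": loops_mep, "GMP": []},
            {"MEP": peaks, "GMP": []},
            {"MEP": atac, "GMP": atac},
        )
        assert len(net.edges["MEP"]) == 3 and len(net.edges["GMP"]) == 0
        enh = [e for e in net.elements if e.kind == "enhancer"]
        assert len(enh) == 3
        for e in enh:
            assert e.looped["MEP"] and not e.looped["GMP"]
            assert len(e.bound_factors["MEP"]) == 2
        table = net.to_table()
        # distal anchor midpoints at +102.5/+152.5/+202.5 kb round half-up
        assert set(table["element_id"]) >= {"GENE1+103", "GENE1+153", "GENE1+203"}
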