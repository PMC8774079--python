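"""Scaffold filtering, pseudogene detection, linkage clustering, loci."""

import warnings

import pytest

from slocus_evo.locus_annotation import (
    Activity,
    GeneClass,
    GeneRecord,
    LocusType,
    SIPhenotype,
    call_loci,
    detect_pseudogene,
    filter_scaffolds,
    gene_gap,
    link_genes,
    loci_table,
    read_gff3,
    summarize_genome,
)


def g(gene_id, scaffold, start, end, gene_class, strand="+", pseudo=False,
      expression=None):
    return GeneRecord(gene_id, scaffold, start, end, strand, gene_class,
                      pseudo=pseudo, expression=expression)


class TestScaffoldFilter:
    LENGTHS = {"a": 800_000, "b": 1_000_000, "c": 5_000_000}

    def test_boundary_inclusive_at_one_megabase(self):
        genes = [
            g("x", "a", 0, 1000, GeneClass.OTHER),
            g("y", "b", 0, 1000, GeneClass.OTHER),
            g("z", "c", 0, 1000, GeneClass.OTHER),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = filter_scaffolds(genes, self.LENGTHS)
        assert [r.gene_id for r in kept] == ["y", "z"]

    def test_missing_length_names_scaffold(self):
        with pytest.raises(ValueError, match="scaffoldX"):
            filter_scaffolds(
                [g("x", "scaffoldX", 0, 10, GeneClass.OTHER)], self.LENGTHS
            )

    def test_empty_input(self):
        assert filter_scaffolds([], self.LENGTHS) == []


class TestPseudogeneDetection:
    @pytest.mark.parametrize(
        "cds, expected",
        [
            ("ATGTAAGGGCCC", True),  # TAA at codon 2
            ("ATGGGGCCCTAA", False),  # terminal stop only
            ("ATGTNAGGGCCC", False),  # ambiguous codon is never a stop
            ("ATGTGACCC", True),
            ("atgtaaggg", True),  # case-insensitive
        ],
    )
    def test_in_frame_stop_rules(self, cds, expected):
        assert detect_pseudogene(cds) is expected

    def test_trailing_remainder_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncat"):
            assert detect_pseudogene("ATGGGGTA") is False

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_pseudogene("AT")


class TestLinkage:
    ANCHOR = g("rnase", "s1", 5_000_000, 5_001_000, GeneClass.T2_RNASE_III)

    def make(self, gap):
        start = self.ANCHOR.end + gap
        return g(f"fb_{gap}", "s1", start, start + 1000, GeneClass.FBX_SLF)

    def test_window_boundary(self):
        inside = self.make(2_900_000)
        boundary = self.make(3_000_000)
        outside = self.make(3_000_001)
        linked = link_genes(self.ANCHOR, [inside, boundary, outside])
        assert linked == [inside, boundary]

    def test_different_scaffold_never_linked(self):
        other = g("fb", "s2", 5_000_000, 5_001_000, GeneClass.FBX_SLF)
        assert link_genes(self.ANCHOR, [other]) == []

    def test_overlap_has_gap_zero(self):
        over = g("fb", "s1", 5_000_500, 5_002_000, GeneClass.FBX_SLF)
        assert gene_gap(self.ANCHOR, over) == 0

    def test_non_rnase_anchor_rejected(self):
        with pytest.raises(ValueError):
            link_genes(self.make(0), [self.ANCHOR])


def _canonical_locus_genes():
    genes = [g("rnase1", "s1", 1_000_000, 1_001_200, GeneClass.T2_RNASE_III)]
    for i in range(2):
        start = 1_050_000 + i * 40_000
        genes.append(g(f"slf{i}", "s1", start, start + 1500, GeneClass.FBX_SLF))
    return genes


class TestCallLoci:
    def test_canonical_active_type1_locus(self):
        loci = call_loci(_canonical_locus_genes())
        assert len(loci) == 1
        locus = loci[0]
        assert locus.locus_type is LocusType.TYPE1_S_LIKE
        assert locus.activity is Activity.ACTIVE
        assert {x.gene_id for x in locus.members} == {"rnase1", "slf0", "slf1"}

    def test_pseudogene_and_low_expression_inactivate(self):
        genes = [
            g("rnase1", "s1", 1_000_000, 1_001_200, GeneClass.T2_RNASE_III),
            g("pslf", "s1", 1_050_000, 1_051_500, GeneClass.FBX_SLF,
              pseudo=True),
            g("slf_low", "s1", 1_100_000, 1_101_500, GeneClass.FBX_SLF,
              expression={"stamen": 0.2}),
        ]
        locus = call_loci(genes)[0]
        # an intact SLF exists, so the locus is nominally active, but all
        # intact SLFs are below the expression threshold: flagged
        assert locus.activity is Activity.ACTIVE
        assert locus.low_expression

    def test_orphan_and_class_i_linked(self):
        genes = [
            g("r3", "s1", 1_000_000, 1_001_000, GeneClass.T2_RNASE_III),
            g("r1", "s2", 1_000_000, 1_001_000, GeneClass.T2_RNASE_I),
            g("fbk", "s2", 1_100_000, 1_101_000, GeneClass.FBX_OTHER),
        ]
        loci = {l.scaffold: l for l in call_loci(genes)}
        assert loci["s1"].locus_type is LocusType.ORPHAN_RNASE
        assert loci["s2"].locus_type is LocusType.CLASSI_II_LINKED

    def test_anchors_sharing_fbox_are_merged(self):
        genes = [
            g("r_a", "s1", 1_000_000, 1_001_000, GeneClass.T2_RNASE_III),
            g("fb", "s1", 2_000_000, 2_001_000, GeneClass.FBX_SLF),
            g("r_b", "s1", 3_000_000, 3_001_000, GeneClass.T2_RNASE_III),
        ]
        loci = call_loci(genes)
        assert len(loci) == 1
        assert len(loci[0].rnases) == 2

    def test_invariant_to_order_and_strand(self):
        genes = _canonical_locus_genes()
        flipped = [
            GeneRecord(x.gene_id, x.scaffold, x.start, x.end,
                       "-" if x.strand == "+" else "+", x.gene_class,
                       pseudo=x.pseudo)
            for x in reversed(genes)
        ]
        a = loci_table(call_loci(genes))
        b = loci_table(call_loci(flipped))
        assert a.equals(b)

    def test_every_rnase_appears_exactly_once(self):
        genes = _canonical_locus_genes() + [
            g("orphan", "s9", 1_000_000, 1_001_000, GeneClass.T2_RNASE_III)
        ]
        loci = call_loci(genes)
        seen = [r.gene_id for l in loci for r in l.rnases]
        assert sorted(seen) == ["orphan", "rnase1"]


class TestSummarize:
    def test_promotion_of_largest_slf_cluster(self):
        big = _canonical_locus_genes()
        small = [
            g("rnase2", "s2", 1_000_000, 1_001_000, GeneClass.T2_RNASE_III),
            g("slf9", "s2", 1_050_000, 1_051_000, GeneClass.FBX_SLF),
        ]
        profile = summarize_genome(
            call_loci(big + small), SIPhenotype.TYPE1_SI, wgd_events=1,
            species="test",
        )
        by_scaffold = {l.scaffold: l.locus_type for l in profile.loci}
        assert by_scaffold == {
            "s1": LocusType.TYPE1_S,
            "s2": LocusType.TYPE1_S_LIKE,
        }

    def test_zero_locus_profile(self):
        profile = summarize_genome([], SIPhenotype.SC)
        assert profile.counts == {}
        assert profile.loci == []


def test_gff3_round_trip_converts_coordinates():
    gff = (
        "##gff-version 3\n"
        "s1\tsim\tgene\t1001\t2000\t.\t+\t.\tID=rnase1;gene_class=T2_RNASE_III\n"
        "s1\tsim\tgene\t5001\t6000\t.\t-\t.\tID=slf1;gene_class=FBX_SLF;pseudo=true\n"
    )
    records = {r.gene_id: r for r in read_gff3(gff, from_string=True)}
    assert records["rnase1"].start == 1000  # 1-based inclusive -> 0-based
    assert records["rnase1"].end == 2000
    assert records["slf1"].strand == "-"
    assert records["slf1"].pseudo is True
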