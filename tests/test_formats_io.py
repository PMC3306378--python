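"""File dialect contracts: parsing, validation, and semantic round-trips."""
import numpy as np
import pandas as pd
import pytest

from pantx import (
    BaseCountTable,
    GeneModel,
    GenotypeMatrix,
    LineGroup,
    ParseError,
    ValidationError,
)
from pantx import formats_io as io
from pantx.snp_calling import discover_snps


class TestBasecountTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "bc.tsv"
        p.write_text(
            "line_id\tchrom\tpos\tcount_A\tcount_C\tcount_G\tcount_T\n"
            "L1\tchr1\t10\t5\t0\t0\t0\n"
        )
        t = io.read_basecount_table(p)
        assert len(t) == 1
        row = t.df.iloc[0]
        assert (row.count_A, row.count_C, row.count_G, row.count_T) == (5, 0, 0, 0)

    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "bc.tsv"
        p.write_text("line_id\tchrom\tpos\tcount_A\tcount_C\tcount_G\tcount_T\n")
        assert len(io.read_basecount_table(p)) == 0

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "bc.tsv"
        p.write_text(
            "line_id\tchrom\tpos\tcount_A\tcount_C\tcount_G\tcount_T\n"
            "L1\tchr1\t10\t-1\t0\t0\t0\n"
        )
        with pytest.raises(ValidationError):
            io.read_basecount_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bc.tsv"
        p.write_text(
            "line_id\tchrom\tpos\tcount_A\tcount_C\tcount_G\tcount_T\n"
            "L1\tchr1\t10\t5\t0\t0\t0\n"
            "L2\tchr1\tten\t5\t0\t0\t0\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            io.read_basecount_table(p)

    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            [("L1", "chr1", 10, 1, 0, 0, 0)] * 2,
            columns=["line_id", "chrom", "pos", "count_A", "count_C", "count_G", "count_T"],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            BaseCountTable(df)

    def test_round_trip(self, tmp_path, small_study):
        table = small_study["basecounts"]
        p = tmp_path / "bc.tsv"
        io.write_basecount_table(table, p)
        assert io.read_basecount_table(p) == table


class TestVcf:
    def _simple_matrix(self):
        loci = pd.DataFrame(
            [("chr1", 10, ("A", "C"))], columns=["chrom", "pos", "confirmed_alleles"]
        )
        calls = pd.DataFrame({"L1": ["A"], "L2": ["A"], "L3": ["C"], "L4": ["C"]})
        return GenotypeMatrix(loci, calls)

    def test_biallelic_encoding(self, tmp_path):
        p = tmp_path / "out.vcf"
        io.write_vcf(self._simple_matrix(), p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        fields = lines[0].split("\t")
        assert fields[3] == "A" and fields[4] == "C"
        assert fields[9:] == ["0/0", "0/0", "1/1", "1/1"]

    def test_triallelic_two_alts(self, tmp_path):
        loci = pd.DataFrame(
            [("chr1", 5, ("A", "C", "G"))], columns=["chrom", "pos", "confirmed_alleles"]
        )
        calls = pd.DataFrame(
            {"L1": ["A"], "L2": ["A"], "L3": ["C"], "L4": ["C"], "L5": ["G"], "L6": ["G"]}
        )
        p = tmp_path / "out.vcf"
        io.write_vcf(GenotypeMatrix(loci, calls), p)
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0].split("\t")
        assert len(row[4].split(",")) == 2
        gts = {g.split("/")[0] for g in row[9:]}
        assert gts == {"0", "1", "2"}

    def test_missing_rendered(self, tmp_path):
        loci = pd.DataFrame(
            [("chr1", 10, ("A", "C"))], columns=["chrom", "pos", "confirmed_alleles"]
        )
        calls = pd.DataFrame({"L1": ["A"], "L2": ["A"], "L3": ["C"], "L4": ["C"], "L5": ["."]})
        p = tmp_path / "out.vcf"
        io.write_vcf(GenotypeMatrix(loci, calls), p)
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0].split("\t")
        assert row[-1] == "./."

    def test_unsorted_loci_rejected(self, tmp_path):
        loci = pd.DataFrame(
            [("chr1", 20, ("A", "C")), ("chr1", 10, ("A", "C"))],
            columns=["chrom", "pos", "confirmed_alleles"],
        )
        calls = pd.DataFrame({"L1": ["A", "A"], "L2": ["A", "A"], "L3": ["C", "C"], "L4": ["C", "C"]})
        with pytest.raises(ValidationError, match="sorted"):
            io.write_vcf(GenotypeMatrix(loci, calls), tmp_path / "x.vcf")

    def test_round_trip_preserves_matrix(self, tmp_path, small_study):
        m = discover_snps(small_study["basecounts"], list(small_study["truth"].lines))
        p = tmp_path / "rt.vcf"
        io.write_vcf(m, p)
        m2 = io.read_vcf(p)
        assert m2.lines == m.lines
        assert m2.calls.equals(m.calls)
        assert [tuple(a) for a in m2.loci["confirmed_alleles"]] == [
            tuple(sorted(a)) for a in m.loci["confirmed_alleles"]
        ]

    def test_structural_validity_under_pysam(self, tmp_path, small_study):
        pysam = pytest.importorskip("pysam")
        m = discover_snps(small_study["basecounts"], list(small_study["truth"].lines))
        p = tmp_path / "check.vcf"
        io.write_vcf(m, p)
        vf = pysam.VariantFile(str(p))
        n = 0
        for rec in vf:
            n += 1
            assert len(rec.samples) == len(m.lines)
            for s in rec.samples.values():
                for idx in s["GT"]:
                    assert idx is None or idx < len(rec.alleles)
        assert n == m.n_loci


GFF = """##gff-version 3
chr1\t.\tgene\t100\t1000\t.\t+\t.\tID=g1
chr1\t.\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\t.\texon\t100\t399\t.\t+\t.\tParent=g1.t1
chr1\t.\texon\t500\t699\t.\t+\t.\tParent=g1.t1
chr1\t.\tmRNA\t100\t900\t.\t+\t.\tID=g1.t2;Parent=g1
chr1\t.\texon\t100\t399\t.\t+\t.\tParent=g1.t2
"""


class TestGff3:
    def test_longest_mrna_exons_retained(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF)
        genes = io.read_gff3_genes(p)
        assert len(genes) == 1
        # t1 has 300+200=500 bp of exon, t2 only 300
        assert genes[0].exons == ((100, 399), (500, 699))
        assert genes[0].exonic_length == 500

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        bad = GFF + "chr1\t.\texon\t950\t1200\t.\t+\t.\tParent=g1.t2\n"
        p = tmp_path / "bad.gff3"
        p.write_text(bad)
        with pytest.raises(ValidationError):
            io.read_gff3_genes(p)


class TestFpkmTable:
    def test_valid_rows(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "gene_id\tline_id\tfpkm\tconf_lo\tconf_hi\n"
            "g1\tL1\t12.0\t8.0\t16.0\n"
            "g2\tL1\t0.0\t0.0\t0.0\n"
        )
        df = io.read_fpkm_table(p)
        assert df["fpkm"].tolist() == [12.0, 0.0]

    def test_lower_bound_above_estimate_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("gene_id\tline_id\tfpkm\tconf_lo\tconf_hi\ng1\tL1\t2.0\t3.0\t4.0\n")
        with pytest.raises(ValidationError):
            io.read_fpkm_table(p)


class TestNewick:
    def test_three_leaf_star(self, tmp_path):
        import skbio

        a, b, c = (skbio.TreeNode(name=n, length=l) for n, l in [("A", 1.0), ("B", 2.0), ("C", 3.0)])
        tree = skbio.TreeNode(children=[a, b, c])
        p = tmp_path / "t.nwk"
        io.write_newick(tree, p)
        text = p.read_text().strip()
        assert text.endswith(";")
        back = io.read_newick(p)
        assert {t.name for t in back.tips()} == {"A", "B", "C"}
        assert back.find("A").length == pytest.approx(1.0)

    def test_round_trip_path_lengths(self, tmp_path, small_study):
        from pantx.diversity import distance_matrix, neighbor_joining
        from pantx.snp_calling import discover_snps

        m = discover_snps(small_study["basecounts"], list(small_study["truth"].lines))
        tree = neighbor_joining(distance_matrix(m, min_shared=50))
        p = tmp_path / "t.nwk"
        io.write_newick(tree, p)
        back = io.read_newick(p)
        d1 = tree.tip_tip_distances()
        d2 = back.tip_tip_distances()
        ids = list(d1.ids)
        assert set(d2.ids) == set(ids)
        np.testing.assert_allclose(
            d1.filter(ids).data, d2.filter(ids).data, atol=1e-9
        )

    def test_duplicate_leaves_rejected(self, tmp_path):
        import skbio

        a1, a2 = skbio.TreeNode(name="A", length=1.0), skbio.TreeNode(name="A", length=2.0)
        b = skbio.TreeNode(name="B", length=1.0)
        with pytest.raises(ValidationError):
            io.write_newick(skbio.TreeNode(children=[a1, a2, b]), tmp_path / "d.nwk")


class TestAuxTables:
    def test_line_group_round_trip(self, tmp_path, small_study):
        groups = small_study["truth"].line_groups
        p = tmp_path / "g.tsv"
        io.write_line_groups(groups, p)
        assert tuple(io.read_line_groups(p)) == groups

    def test_bad_group_label_rejected(self):
        with pytest.raises(ValidationError):
            LineGroup("L1", "Dent")

    def test_alignment_summary_round_trip(self, tmp_path, small_study):
        summaries = small_study["alignments"]
        p = tmp_path / "a.tsv"
        io.write_alignment_summaries(summaries, p)
        assert io.read_alignment_summaries(p) == summaries

    def test_read_support_round_trip(self, tmp_path, small_study):
        sup = small_study["read_support"]
        p = tmp_path / "s.tsv"
        io.write_read_support(sup, p)
        assert io.read_read_support(p).equals(sup)
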