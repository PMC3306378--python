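"""SNP caller rules: per-line thresholds, allele confirmation, discovery,
and the derived per-gene / per-window statistics."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_basecount_table
from pantx import BaseCountTable, GeneModel, MISSING
from pantx.snp_calling import (
    call_line_genotype,
    confirm_alleles,
    discover_snps,
    per_line_coverage_stats,
    snp_gene_stats,
    window_density,
)


class TestCallLineGenotype:
    @pytest.mark.parametrize(
        "counts, allele, passing",
        [
            ((10, 0, 0, 0), "A", {"A"}),
            # 1 read of C fails both rules: 1 < 2 and 1/20 = 5% is not > 5%
            ((19, 1, 0, 0), "A", {"A"}),
            # 2 reads of C pass both rules (2/32 = 6.25% > 5%) -> two alleles -> missing
            ((30, 2, 0, 0), MISSING, {"A", "C"}),
            ((0, 0, 0, 0), MISSING, set()),
        ],
    )
    def test_rule_boundaries(self, counts, allele, passing):
        got_allele, got_passing = call_line_genotype(counts)
        assert got_allele == allele
        assert got_passing == passing

    def test_exact_five_percent_fails(self):
        # 2/40 = 5.0% exactly: the fraction rule is strict
        allele, passing = call_line_genotype((38, 2, 0, 0))
        assert allele == "A" and passing == {"A"}

    def test_exhaustive_small_totals_match_brute_force(self):
        """Every count vector with total <= 40 agrees with a plain
        restatement of the two thresholds."""
        for total in range(41):
            for a in range(total + 1):
                for c in range(total - a + 1):
                    for g in range(total - a - c + 1):
                        counts = (a, c, g, total - a - c - g)
                        expect = oracles.brute_call(counts)
                        got_allele, got_passing = call_line_genotype(counts)
                        assert (got_allele, set(got_passing)) == expect, counts

    def test_negative_counts_rejected(self):
        with pytest.raises(Exception):
            call_line_genotype((-1, 0, 0, 0))


class TestConfirmAlleles:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (["A", "A", "C", "C"], {"A", "C"}),  # two lines per allele
            (["A", "A", "A", "C"], {"A"}),  # C seen once: unconfirmed
            ([MISSING] * 4, set()),
        ],
    )
    def test_two_line_support(self, calls, expected):
        assert confirm_alleles(calls) == expected


class TestDiscoverSnps:
    def _table(self, rows):
        return BaseCountTable(
            pd.DataFrame(
                rows,
                columns=["line_id", "chrom", "pos", "count_A", "count_C", "count_G", "count_T"],
            )
        )

    def test_biallelic_two_lines_each(self):
        rows = [
            ("L1", "chr1", 10, 9, 0, 0, 0),
            ("L2", "chr1", 10, 8, 0, 0, 0),
            ("L3", "chr1", 10, 0, 7, 0, 0),
            ("L4", "chr1", 10, 0, 9, 0, 0),
        ]
        m = discover_snps(self._table(rows), ["L1", "L2", "L3", "L4"])
        assert m.n_loci == 1
        assert m.loci["confirmed_alleles"].iloc[0] == ("A", "C")
        assert list(m.calls.iloc[0]) == ["A", "A", "C", "C"]

    def test_monomorphic_panel_yields_no_locus(self):
        rows = [(f"L{i}", "chr1", 5, 20, 0, 0, 0) for i in range(21)]
        m = discover_snps(self._table(rows), [f"L{i}" for i in range(21)])
        assert m.n_loci == 0

    def test_single_line_allele_not_confirmed_but_call_retained(self):
        rows = [
            ("L1", "chr1", 10, 9, 0, 0, 0),
            ("L2", "chr1", 10, 8, 0, 0, 0),
            ("L3", "chr1", 10, 0, 7, 0, 0),
            ("L4", "chr1", 10, 0, 9, 0, 0),
            ("L5", "chr1", 10, 0, 0, 9, 0),  # G carried by one line only
        ]
        m = discover_snps(self._table(rows), ["L1", "L2", "L3", "L4", "L5"])
        assert m.loci["confirmed_alleles"].iloc[0] == ("A", "C")
        assert m.calls.iloc[0]["L5"] == "G"
        assert bool(m.unconfirmed.iloc[0]["L5"])
        assert not m.unconfirmed.iloc[0]["L1"]

    def test_random_tables_match_brute_force(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            table, records, lines = random_basecount_table(rng, n_lines=6, n_positions=50)
            m = discover_snps(table, lines)
            expect = oracles.brute_discover(records, lines)
            got = [
                (c, int(p), tuple(al), list(m.calls.iloc[i]))
                for i, (c, p, al) in enumerate(
                    zip(m.loci["chrom"], m.loci["pos"], m.loci["confirmed_alleles"])
                )
            ]
            assert got == expect

    def test_every_locus_has_at_least_four_informative_lines(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            table, _, lines = random_basecount_table(rng, n_lines=8, n_positions=40)
            m = discover_snps(table, lines)
            non_missing = (m.calls != MISSING).sum(axis=1)
            assert (non_missing >= 4).all()

    @settings(max_examples=100, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=4, max_size=4),
        extra=st.integers(1, 20),
    )
    def test_adding_reads_of_passing_allele_keeps_call(self, counts, extra):
        allele, _ = call_line_genotype(counts)
        if allele == MISSING:
            return
        idx = "ACGT".index(allele)
        boosted = list(counts)
        boosted[idx] += extra
        assert call_line_genotype(boosted)[0] == allele

    def test_adding_supporting_line_never_removes_locus(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table, records, lines = random_basecount_table(rng, n_lines=5, n_positions=20)
            m = discover_snps(table, lines)
            if m.n_loci == 0:
                continue
            chrom, pos = m.loci["chrom"].iloc[0], int(m.loci["pos"].iloc[0])
            allele = m.loci["confirmed_alleles"].iloc[0][0]
            counts = [0, 0, 0, 0]
            counts["ACGT".index(allele)] = 20
            extra = pd.DataFrame(
                [("Lnew", chrom, pos, *counts)], columns=table.df.columns
            )
            table2 = BaseCountTable(pd.concat([table.df, extra], ignore_index=True))
            m2 = discover_snps(table2, lines + ["Lnew"])
            assert (chrom, pos) in set(zip(m2.loci["chrom"], m2.loci["pos"]))


def _gene(gene_id="g1", chrom="chr1", exons=((1, 500), (701, 1200))):
    return GeneModel(gene_id, chrom, exons[0][0], exons[-1][1], "+", tuple(exons))


def _matrix_at(positions, chrom="chr1"):
    """Minimal genotype matrix with loci at the given positions."""
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": sorted(positions), "confirmed_alleles": [("A", "C")] * len(positions)}
    )
    calls = pd.DataFrame({"L1": ["A"] * len(positions), "L2": ["C"] * len(positions)})
    from pantx import GenotypeMatrix

    return GenotypeMatrix(loci, calls)


class TestSnpGeneStats:
    def test_density_per_100bp(self):
        gene = _gene()  # exonic length 1000
        m = _matrix_at([10, 20, 30, 800, 900])
        stats, n_un = snp_gene_stats(m, [gene])
        assert stats["snp_count"].iloc[0] == 5
        assert stats["snps_per_100bp"].iloc[0] == pytest.approx(0.5)
        assert n_un == 0

    def test_intronic_snp_not_assigned(self):
        gene = _gene()
        m = _matrix_at([600])  # between the two exons
        stats, n_un = snp_gene_stats(m, [gene])
        assert stats["snp_count"].iloc[0] == 0
        assert n_un == 1

    def test_random_placement_matches_interval_containment(self):
        rng = np.random.default_rng(3)
        genes = [
            _gene("g1", exons=((50, 149), (200, 299))),
            _gene("g2", exons=((120, 400),)),  # overlaps g1
            _gene("g3", "chr2", exons=((10, 100),)),
        ]
        positions = sorted(int(p) for p in rng.choice(np.arange(1, 450), 60, replace=False))
        m = _matrix_at(positions)
        stats, n_un = snp_gene_stats(m, genes)
        for g in genes:
            expect = sum(
                1 for p in positions if g.chrom == "chr1" and g.contains_exonic(p)
            )
            assert stats.set_index("gene_id").loc[g.gene_id, "snp_count"] == expect
        expect_un = sum(
            1
            for p in positions
            if not any(g.chrom == "chr1" and g.contains_exonic(p) for g in genes)
        )
        assert n_un == expect_un


class TestWindowDensity:
    def _fpkm(self, gene_id, lines_expressed, all_lines):
        return pd.DataFrame(
            [
                (gene_id, l, 1.0, 0.5 if l in lines_expressed else 0.0, 2.0)
                for l in all_lines
            ],
            columns=["gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"],
        )

    def test_three_line_expression_is_not_enough(self):
        gene = _gene()
        lines = [f"L{i}" for i in range(6)]
        m = _matrix_at([10])
        fpkm3 = self._fpkm("g1", lines[:3], lines)
        fpkm4 = self._fpkm("g1", lines[:4], lines)
        w3 = window_density(m, [gene], fpkm3)
        w4 = window_density(m, [gene], fpkm4)
        assert w3["n_expressed_genes"].iloc[0] == 0
        assert w4["n_expressed_genes"].iloc[0] == 1

    def test_position_one_lands_in_first_window(self):
        m = _matrix_at([1])
        w = window_density(m, [])
        assert len(w) == 1
        assert w.iloc[0]["window"] == 0 and w.iloc[0]["n_snps"] == 1

    def test_random_binning_matches_brute_force(self):
        rng = np.random.default_rng(5)
        positions = sorted(int(p) for p in rng.choice(np.arange(1, 10_000), 80, replace=False))
        m = _matrix_at(positions)
        genes = [
            _gene(f"g{i}", exons=((s, s + 99),))
            for i, s in enumerate(rng.choice(np.arange(1, 9_000), 15, replace=False))
        ]
        w = window_density(m, genes, window=1000)
        for _, row in w.iterrows():
            lo, hi = row["start"], row["end"]
            assert row["n_snps"] == sum(lo <= p <= hi for p in positions)
            assert row["n_genes"] == sum(lo <= g.midpoint <= hi for g in genes)


class TestPerLineCoverage:
    def test_full_and_zero_coverage(self):
        rows = [
            ("L1", "chr1", 10, 9, 0, 0, 0),
            ("L2", "chr1", 10, 8, 0, 0, 0),
            ("L3", "chr1", 10, 0, 7, 0, 0),
            ("L4", "chr1", 10, 0, 9, 0, 0),
        ]
        table = BaseCountTable(
            pd.DataFrame(rows, columns=["line_id", "chrom", "pos", "count_A", "count_C", "count_G", "count_T"])
        )
        m = discover_snps(table, ["L1", "L2", "L3", "L4", "L5"])
        gene = _gene()
        stats = per_line_coverage_stats(table, m, [gene]).set_index("line_id")
        assert stats.loc["L1", "pct_snp_loci_covered"] == 100.0
        assert stats.loc["L1", "pct_snp_genes_covered"] == 100.0
        assert stats.loc["L5", "pct_snp_loci_covered"] == 0.0
        assert stats.loc["L5", "pct_snp_genes_covered"] == 0.0

    def test_random_tables_match_brute_force(self):
        for seed in range(30):  # first seed whose draw contains SNP loci
            rng = np.random.default_rng(seed)
            table, records, lines = random_basecount_table(rng, n_lines=6, n_positions=40)
            m = discover_snps(table, lines)
            if m.n_loci:
                break
        assert m.n_loci > 0
        genes = [_gene("g1", exons=((1, 200),)), _gene("g2", "chr2", exons=((1, 200),))]
        stats = per_line_coverage_stats(table, m, genes).set_index("line_id")
        snp_loci = list(zip(m.loci["chrom"], m.loci["pos"]))
        for line in lines:
            covered = [
                (c, p) for (c, p) in snp_loci if sum(records.get((line, c, p), (0,))) > 0
            ]
            assert stats.loc[line, "pct_snp_loci_covered"] == pytest.approx(
                100 * len(covered) / len(snp_loci)
            )
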