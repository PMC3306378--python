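#!/usr/bin/env python
"""Call SNPs from the simulated base counts and summarise their distribution.

Applies the three-rule caller (>5% of filtered reads and >=2 reads per
line; >=2 lines per allele; >=2 alleles per locus), writes the genotype
matrix as VCF, and derives per-gene SNP counts and densities, 100-kb window
densities, and per-line coverage statistics.
"""
from pathlib import Path

from pantx import formats_io as io
from pantx import snp_calling as snp

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    table = io.read_basecount_table(STUDY / "basecounts.tsv")
    genes = io.read_gff3_genes(STUDY / "genes.gff3")
    matrix = snp.discover_snps(table)
    io.write_vcf(matrix, OUT / "snps.vcf")
    print(f"{matrix.n_loci} SNP loci called across {len(matrix.lines)} lines")

    stats, n_unassigned = snp.snp_gene_stats(matrix, genes)
    stats.to_csv(OUT / "snp_gene_stats.tsv", sep="\t", index=False)
    with_snp = (stats["snp_count"] > 0).sum()
    print(f"{with_snp}/{len(genes)} genes carry >=1 SNP "
          f"(max {stats['snp_count'].max()} per gene, {n_unassigned} loci outside genes)")
    print(f"median density {stats.loc[stats.snp_count > 0, 'snps_per_100bp'].median():.2f} SNPs/100bp")

    fpkm = io.read_fpkm_table(STUDY / "fpkm.tsv")
    windows = snp.window_density(matrix, genes, fpkm, window=50_000)
    windows.to_csv(OUT / "window_density.tsv", sep="\t", index=False)
    print(f"{len(windows)} windows of 50 kb; "
          f"{windows['n_snps'].sum()} SNPs over {windows['n_genes'].sum()} genes, "
          f"{windows['n_expressed_genes'].sum()} expressed (>=4 lines)")

    coverage = snp.per_line_coverage_stats(table, matrix, genes)
    coverage.to_csv(OUT / "per_line_snp_coverage.tsv", sep="\t", index=False)
    print(f"per-line SNP-locus coverage "
          f"{coverage['pct_snp_loci_covered'].min():.1f}%"
          f"-{coverage['pct_snp_loci_covered'].max():.1f}%")


if __name__ == "__main__":
    main()
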