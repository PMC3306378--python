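#!/usr/bin/env python
"""Partition the gene space into core, dispensable and silent transcriptomes.

A gene is expressed in a line when its FPKM 95% CI lower bound exceeds
zero.  This script writes the lines-expressed histogram, the per-line
summary (percent expressed, maximum FPKM), the semi-quantitative category
matrix (no/low/medium/high at FPKM 5 and 200), and the
constitutive/variable split.
"""
from pathlib import Path

import pandas as pd

from pantx import formats_io as io
from pantx import expression_profile as expr

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    fpkm = expr.densify_fpkm(io.read_fpkm_table(STUDY / "fpkm.tsv"))
    n_lines = fpkm["line_id"].nunique()

    hist = expr.core_dispensable_histogram(fpkm)
    hist.rename_axis("n_lines_expressed").to_csv(OUT / "expression_histogram.tsv", sep="\t")
    total = hist.sum()
    core, disp, silent = hist.iloc[n_lines], hist.iloc[1:n_lines].sum(), hist.iloc[0]
    print(f"{core} ({100 * core / total:.1f}%) genes expressed in all {n_lines} lines (core)")
    print(f"{disp} ({100 * disp / total:.1f}%) genes expressed in 1-{n_lines - 1} lines (dispensable)")
    print(f"{silent} ({100 * silent / total:.1f}%) genes expressed in none")

    cats = expr.category_matrix(fpkm)
    cats.map(lambda c: c.value).to_csv(OUT / "expression_categories.tsv", sep="\t")
    n_const, per_cat, n_var = expr.constitutive_variable_partition(cats)
    print(f"{n_const} genes constitutive across all lines "
          f"({ {c.value: n for c, n in per_cat.items() if n} }), {n_var} variable")

    summary = expr.per_line_summary(fpkm)
    summary.to_csv(OUT / "per_line_expression.tsv", sep="\t", index=False)
    print(f"percent genes expressed per line: "
          f"{summary['pct_genes_expressed'].min():.2f}%-{summary['pct_genes_expressed'].max():.2f}%")
    top = summary.loc[summary["max_fpkm"].idxmax()]
    print(f"panel maximum FPKM {top['max_fpkm']:.1f} ({top['max_fpkm_gene']} in {top['line_id']})")


if __name__ == "__main__":
    main()
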