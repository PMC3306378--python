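"""Expression classification from FPKM confidence intervals.

A gene is *expressed* in a line when the lower bound of its 95% FPKM
confidence interval exceeds zero — a literal zero lower bound is the
not-expressed signature (no epsilon).  On top of the binary call sits a
semi-quantitative binning at FPKM 5 and 200, and panel-level partitions:
the core transcriptome (expressed in every line), the dispensable
transcriptome (expressed in a proper nonempty subset), and the
constitutive/variable split of the category matrix.
"""
from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from ._model import ExpressionCategory, FPKMRecord, ValidationError, fpkm_frame

__all__ = [
    "FPKMRecord",
    "ExpressionCategory",
    "expression_call",
    "semiquant_category",
    "expressed_matrix",
    "category_matrix",
    "densify_fpkm",
    "core_dispensable_histogram",
    "constitutive_variable_partition",
    "per_line_summary",
]

LOW_MAX_FPKM = 5.0
HIGH_MIN_FPKM = 200.0


def expression_call(record: FPKMRecord) -> bool:
    """True iff the 95% CI lower bound is strictly greater than zero."""
    return record.conf_lo > 0


def semiquant_category(record: FPKMRecord) -> ExpressionCategory:
    """NONE if conf_lo == 0; else LOW (<5), MEDIUM (5..200 inclusive), HIGH (>200)."""
    if record.conf_lo == 0:
        return ExpressionCategory.NONE
    if record.fpkm < LOW_MAX_FPKM:
        return ExpressionCategory.LOW
    if record.fpkm <= HIGH_MIN_FPKM:
        return ExpressionCategory.MEDIUM
    return ExpressionCategory.HIGH


def densify_fpkm(df: pd.DataFrame, lines: Iterable[str] | None = None) -> pd.DataFrame:
    """Fill missing gene x line cells with (0, 0, 0), warning once.

    Genes absent from a line's FPKM output are treated as not expressed.
    """
    df = fpkm_frame(df)
    genes = sorted(df["gene_id"].unique())
    lines = sorted(df["line_id"].unique()) if lines is None else list(lines)
    full = pd.MultiIndex.from_product([genes, lines], names=["gene_id", "line_id"])
    indexed = df.set_index(["gene_id", "line_id"])
    if indexed.index.has_duplicates:
        raise ValidationError("duplicate gene x line FPKM records")
    n_missing = len(full) - len(indexed.index.intersection(full))
    if n_missing:
        warnings.warn(f"densifying {n_missing} absent gene x line cells to (0,0,0)")
    out = indexed.reindex(full, fill_value=0.0).reset_index()
    return out


def _pivot(df: pd.DataFrame, values: pd.Series) -> pd.DataFrame:
    wide = df.assign(_v=values).pivot(index="gene_id", columns="line_id", values="_v")
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise ValidationError(f"incomplete matrix: gene {gene} lacks a record for some line")
    return wide


def expressed_matrix(records: Iterable[FPKMRecord] | pd.DataFrame) -> pd.DataFrame:
    """Gene x line boolean matrix of expression calls (complete input required)."""
    df = fpkm_frame(records)
    return _pivot(df, df["conf_lo"] > 0)


def category_matrix(records: Iterable[FPKMRecord] | pd.DataFrame) -> pd.DataFrame:
    """Gene x line matrix of semi-quantitative categories."""
    df = fpkm_frame(records)
    cat = np.select(
        [
            df["conf_lo"] == 0,
            df["fpkm"] < LOW_MAX_FPKM,
            df["fpkm"] <= HIGH_MIN_FPKM,
        ],
        [ExpressionCategory.NONE, ExpressionCategory.LOW, ExpressionCategory.MEDIUM],
        default=ExpressionCategory.HIGH,
    )
    return _pivot(df, pd.Series(cat, index=df.index))


def core_dispensable_histogram(
    records: Iterable[FPKMRecord] | pd.DataFrame,
) -> pd.Series:
    """Histogram: number of lines a gene is expressed in -> gene count.

    Bucket N (all lines) is the core transcriptome, buckets 1..N-1 the
    dispensable transcriptome, bucket 0 the never-expressed set; the
    buckets sum to the total gene count.  Every gene must carry a record
    for every line (use :func:`densify_fpkm` first if needed).
    """
    wide = expressed_matrix(records)
    n_lines = wide.shape[1]
    counts = wide.sum(axis=1).value_counts()
    return counts.reindex(range(n_lines + 1), fill_value=0).rename("n_genes")


def constitutive_variable_partition(
    categories: pd.DataFrame,
) -> tuple[int, dict[ExpressionCategory, int], int]:
    """Split genes into constitutive (one category across every line,
    including NONE) and variable; returns (n_constitutive, per-category
    constitutive counts, n_variable)."""
    per_cat = {c: 0 for c in ExpressionCategory}
    n_const = 0
    for _, row in categories.iterrows():
        cats = set(row)
        if len(cats) == 1:
            n_const += 1
            per_cat[next(iter(cats))] += 1
    return n_const, per_cat, len(categories) - n_const


def per_line_summary(
    records: Iterable[FPKMRecord] | pd.DataFrame,
    *,
    n_total_genes: int | None = None,
) -> pd.DataFrame:
    """Per line: % of genes expressed, maximum FPKM, and the gene attaining it.

    The percentage denominator is the annotated gene total, an input
    property; by default the number of distinct genes in the table.
    Ties in the maximum break toward the lexicographically first gene_id.
    """
    df = fpkm_frame(records)
    if n_total_genes is None:
        n_total_genes = df["gene_id"].nunique()
    rows = []
    for line, sub in df.groupby("line_id"):
        n_expr = int((sub["conf_lo"] > 0).sum())
        sub = sub.sort_values(["fpkm", "gene_id"], ascending=[False, True])
        top = sub.iloc[0]
        rows.append((line, 100.0 * n_expr / n_total_genes, float(top["fpkm"]), top["gene_id"]))
    return pd.DataFrame(
        rows, columns=["line_id", "pct_genes_expressed", "max_fpkm", "max_fpkm_gene"]
    ).sort_values("line_id").reset_index(drop=True)
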