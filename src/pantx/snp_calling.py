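"""Multi-line SNP discovery from RNA-seq base-count pileups.

The caller operates on per-line counts of quality-filtered reads at each
genomic position and applies three rules:

1. *Per-line genotype*: a nucleotide is accepted for a line when it is
   supported by at least ``min_reads`` reads (default 2) **and** by strictly
   more than ``min_frac`` (default 5.0%) of that line's filtered reads at the
   position.  A line with zero or with two or more accepted nucleotides is
   scored MISSING — in a (nearly) homozygous inbred a multi-allele call is
   indistinguishable from a collapsed paralog.
2. *Allele confirmation*: an allele exists at a position only if at least
   ``min_lines`` (default 2) lines carry it as their single called base.
3. *SNP emission*: a position is a SNP locus only if at least two confirmed
   alleles remain.  It follows that every emitted locus has non-missing data
   in at least four lines.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._model import (
    BASES,
    BASE_INDEX,
    MISSING,
    BaseCountTable,
    GeneModel,
    GenotypeCall,
    GenotypeMatrix,
    ValidationError,
    fpkm_frame,
)

__all__ = [
    "BaseCountTable",
    "GenotypeCall",
    "GenotypeMatrix",
    "call_line_genotype",
    "call_genotypes_table",
    "confirm_alleles",
    "discover_snps",
    "snp_gene_stats",
    "window_density",
    "per_line_coverage_stats",
]

#: Default thresholds: >5.0% of filtered reads, >=2 reads, >=2 lines per
#: allele, >=2 alleles per locus.
DEFAULT_MIN_FRAC = 0.05
DEFAULT_MIN_READS = 2
DEFAULT_MIN_LINES = 2
DEFAULT_MIN_ALLELES = 2


def _passing_mask(counts: np.ndarray, min_reads: int, min_frac: float) -> np.ndarray:
    """Boolean (..., 4) mask of nucleotides meeting both per-line thresholds.

    The denominator of the fraction rule is the sum of the four post-filter
    base counts at the position for that line.
    """
    counts = np.asarray(counts)
    total = counts.sum(axis=-1, keepdims=True)
    return (counts >= min_reads) & (counts > min_frac * total)


def call_line_genotype(
    counts: Sequence[int],
    *,
    min_reads: int = DEFAULT_MIN_READS,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> tuple[str, frozenset[str]]:
    """Call one line's genotype from its (A, C, G, T) read counts.

    Returns ``(allele, passing_alleles)`` where ``allele`` is a nucleotide
    when exactly one passes both thresholds and MISSING otherwise
    (including the all-zero, no-coverage case).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (4,):
        raise ValidationError("expected four counts (A, C, G, T)")
    if (counts < 0).any():
        raise ValidationError("negative base count")
    mask = _passing_mask(counts, min_reads, min_frac)
    passing = frozenset(b for b, m in zip(BASES, mask) if m)
    allele = next(iter(passing)) if len(passing) == 1 else MISSING
    return allele, passing


def confirm_alleles(
    calls: Iterable[GenotypeCall | str],
    *,
    min_lines: int = DEFAULT_MIN_LINES,
) -> set[str]:
    """Alleles supported, as the single non-missing call, by >= min_lines lines.

    Accepts either :class:`GenotypeCall` objects or bare allele strings.
    """
    tally: dict[str, int] = {}
    for c in calls:
        allele = c.allele if isinstance(c, GenotypeCall) else c
        if allele != MISSING:
            tally[allele] = tally.get(allele, 0) + 1
    return {a for a, n in tally.items() if n >= min_lines}


def _code_calls(counts: np.ndarray, min_reads: int, min_frac: float) -> np.ndarray:
    """Vectorised genotype codes: 0..3 = A,C,G,T; -1 = MISSING."""
    mask = _passing_mask(counts, min_reads, min_frac)
    n_pass = mask.sum(axis=-1)
    codes = np.where(n_pass == 1, mask.argmax(axis=-1), -1)
    return codes.astype(np.int8)


def call_genotypes_table(
    table: BaseCountTable,
    lines: Sequence[str] | None = None,
    *,
    min_reads: int = DEFAULT_MIN_READS,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> pd.DataFrame:
    """Per-line genotype calls at every covered position, monomorphic or not.

    Applies only the per-line rule (no allele confirmation or SNP
    emission); used e.g. to score raw calls against a reference sequence.
    Returns tidy non-missing calls: chrom, pos, line_id, allele.
    """
    lines = list(lines) if lines is not None else table.lines
    loci, counts = table.pivot(lines)
    codes = _code_calls(counts, min_reads, min_frac)
    pi, li = np.nonzero(codes >= 0)
    return pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy()[pi],
            "pos": loci["pos"].to_numpy()[pi],
            "line_id": np.asarray(lines, dtype=object)[li],
            "allele": np.asarray(BASES)[codes[pi, li]],
        }
    )


def discover_snps(
    table: BaseCountTable,
    lines: Sequence[str] | None = None,
    *,
    min_reads: int = DEFAULT_MIN_READS,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_lines: int = DEFAULT_MIN_LINES,
    min_alleles: int = DEFAULT_MIN_ALLELES,
) -> GenotypeMatrix:
    """Apply the full three-rule caller to a base-count table.

    Per-line calls that fail the two-line confirmation at an emitted locus
    are retained in the matrix and flagged ``unconfirmed``; the confirmation
    rule gates locus emission, not individual calls.
    Loci are sorted by (chrom, pos).
    """
    lines = list(lines) if lines is not None else table.lines
    loci, counts = table.pivot(lines)
    if len(loci) == 0:
        empty = pd.DataFrame(columns=["chrom", "pos", "confirmed_alleles"])
        return GenotypeMatrix(empty, pd.DataFrame(columns=lines))

    codes = _code_calls(counts, min_reads, min_frac)  # (n_loci, n_lines)
    per_allele_lines = np.stack([(codes == a).sum(axis=1) for a in range(4)], axis=1)
    confirmed = per_allele_lines >= min_lines  # (n_loci, 4)
    keep = confirmed.sum(axis=1) >= min_alleles

    kept_codes = codes[keep]
    kept_conf = confirmed[keep]
    loci_out = loci[keep].reset_index(drop=True)
    loci_out["confirmed_alleles"] = [
        tuple(BASES[a] for a in range(4) if row[a]) for row in kept_conf
    ]
    letters = np.array(list(BASES) + [MISSING])
    calls = pd.DataFrame(letters[kept_codes], columns=lines)
    called = kept_codes >= 0
    conf_of_call = np.zeros_like(called)
    conf_of_call[called] = kept_conf[np.nonzero(called)[0], kept_codes[called]]
    unconfirmed = pd.DataFrame(called & ~conf_of_call, columns=lines)
    return GenotypeMatrix(loci_out, calls, unconfirmed)


def snp_gene_stats(
    matrix: GenotypeMatrix,
    genes: Sequence[GeneModel],
    *,
    by: str = "exon",
) -> tuple[pd.DataFrame, int]:
    """Per-gene SNP count and density per 100 bp of exonic gene length.

    A SNP is assigned to every gene whose exon set (or gene span, with
    ``by='span'``) contains its position; a locus inside no gene counts
    toward the returned ``n_unassigned``.  Density divides by the summed
    exon length of the longest mRNA, in units of SNPs per 100 bp.
    """
    if by not in ("exon", "span"):
        raise ValidationError("by must be 'exon' or 'span'")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in matrix.loci.groupby("chrom"):
        pos_by_chrom[chrom] = np.sort(sub["pos"].to_numpy())
    assigned_any: dict[str, set] = {c: set() for c in pos_by_chrom}

    rows = []
    for g in genes:
        pos = pos_by_chrom.get(g.chrom)
        n = 0
        if pos is not None:
            intervals = g.exons if by == "exon" else ((g.start, g.end),)
            for s, e in intervals:
                lo, hi = np.searchsorted(pos, [s, e + 1])
                n += hi - lo
                assigned_any[g.chrom].update(pos[lo:hi].tolist())
        rows.append((g.gene_id, n, n / (g.exonic_length / 100.0)))
    stats = pd.DataFrame(rows, columns=["gene_id", "snp_count", "snps_per_100bp"])
    n_unassigned = sum(
        len(pos) - len(assigned_any.get(chrom, ()))
        for chrom, pos in pos_by_chrom.items()
    )
    return stats, n_unassigned


def window_density(
    matrix: GenotypeMatrix,
    genes: Sequence[GeneModel],
    fpkm: pd.DataFrame | None = None,
    *,
    window: int = 1_000_000,
    min_expressed_lines: int = 4,
) -> pd.DataFrame:
    """SNP, gene, and expressed-gene counts in fixed genomic windows.

    Windows cover [k*w+1, (k+1)*w]; SNPs are binned by position and genes by
    midpoint.  A gene counts as expressed when at least ``min_expressed_lines``
    lines (default 4, matching the minimum line count at which a SNP can be
    called) have an FPKM confidence-interval lower bound above zero.
    """
    expressed_genes: set[str] = set()
    if fpkm is not None:
        df = fpkm_frame(fpkm)
        n_expr = df[df["conf_lo"] > 0].groupby("gene_id")["line_id"].nunique()
        expressed_genes = set(n_expr[n_expr >= min_expressed_lines].index)

    def win(pos: int) -> int:
        return (pos - 1) // window

    counts: dict[tuple[str, int], list[int]] = {}

    def bucket(chrom: str, w: int) -> list[int]:
        return counts.setdefault((chrom, w), [0, 0, 0])

    for chrom, pos in zip(matrix.loci["chrom"], matrix.loci["pos"]):
        bucket(chrom, win(int(pos)))[0] += 1
    for g in genes:
        b = bucket(g.chrom, win(g.midpoint))
        b[1] += 1
        if g.gene_id in expressed_genes:
            b[2] += 1
    rows = [
        (chrom, w, w * window + 1, (w + 1) * window, c[0], c[1], c[2])
        for (chrom, w), c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "window", "start", "end", "n_snps", "n_genes", "n_expressed_genes"],
    )


def per_line_coverage_stats(
    table: BaseCountTable,
    matrix: GenotypeMatrix,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per line: % of SNP loci with read coverage and % of SNP-containing
    genes with at least one covered polymorphic locus.

    Coverage at a locus means at least one filtered read of any nucleotide.
    The gene denominator is the set of genes whose exons contain >= 1 SNP
    locus.
    """
    lines = matrix.lines
    loci, counts = table.pivot(lines)
    key = {(c, p): i for i, (c, p) in enumerate(zip(loci["chrom"], loci["pos"]))}
    snp_idx = np.array(
        [key.get((c, p), -1) for c, p in zip(matrix.loci["chrom"], matrix.loci["pos"])]
    )
    depth = counts.sum(axis=2)  # (n_table_loci, n_lines)
    covered = np.zeros((matrix.n_loci, len(lines)), dtype=bool)
    present = snp_idx >= 0
    covered[present] = depth[snp_idx[present]] > 0

    # map each SNP locus to the genes containing it (exonic containment)
    snp_pos = list(zip(matrix.loci["chrom"], matrix.loci["pos"]))
    gene_loci: dict[str, list[int]] = {}
    for g in genes:
        hits = [
            i for i, (c, p) in enumerate(snp_pos) if c == g.chrom and g.contains_exonic(int(p))
        ]
        if hits:
            gene_loci[g.gene_id] = hits

    rows = []
    for j, line in enumerate(lines):
        pct_loci = 100.0 * covered[:, j].mean() if matrix.n_loci else float("nan")
        if gene_loci:
            n_genes_cov = sum(1 for hits in gene_loci.values() if covered[hits, j].any())
            pct_genes = 100.0 * n_genes_cov / len(gene_loci)
        else:
            pct_genes = float("nan")
        rows.append((line, pct_loci, pct_genes))
    return pd.DataFrame(
        rows, columns=["line_id", "pct_snp_loci_covered", "pct_snp_genes_covered"]
    )
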