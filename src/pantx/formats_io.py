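"""Readers and writers for every external representation the pipeline touches.

All external coordinates are 1-based inclusive (GFF3/VCF convention).  The
TSV dialects defined here are deliberately minimal: tab-separated, one
header line, no quoting.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import skbio

from ._model import (
    BASES,
    BASECOUNT_COLUMNS,
    GROUPS,
    MISSING,
    AlignmentSummary,
    BaseCountTable,
    FPKMRecord,
    GeneModel,
    GenotypeMatrix,
    LineGroup,
    ParseError,
    ValidationError,
)

__all__ = [
    "GeneModel",
    "LineGroup",
    "read_basecount_table",
    "write_basecount_table",
    "read_gff3_genes",
    "read_fpkm_table",
    "write_fpkm_table",
    "write_vcf",
    "read_vcf",
    "write_newick",
    "read_newick",
    "read_line_groups",
    "write_line_groups",
    "read_alignment_summaries",
    "write_alignment_summaries",
    "read_read_support",
    "write_read_support",
]


def _read_tsv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != list(columns):
        raise ParseError(f"{path}: expected header {list(columns)}, got {header}")
    try:
        return pd.read_csv(
            path,
            sep="\t",
            float_precision="round_trip",
            dtype={c: str for c in ("line_id", "chrom", "gene_id", "transcript_id", "group") if c in columns},
        )
    except Exception as exc:  # malformed body
        raise ParseError(f"{path}: {exc}") from exc


def read_basecount_table(path) -> BaseCountTable:
    """Read the per-base count TSV dialect.

    Columns: line_id, chrom, pos, count_A, count_C, count_G, count_T.
    Duplicate (line, chrom, pos) keys and negative counts are rejected.
    """
    path = Path(path)
    df = _read_tsv(path, BASECOUNT_COLUMNS)
    for i, (col, kind) in enumerate(
        [("pos", int), ("count_A", int), ("count_C", int), ("count_G", int), ("count_T", int)]
    ):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = (bad.index[0] + 2) if len(bad) else "?"
            raise ParseError(f"{path}: non-integer {col} at line {lineno}") from exc
    return BaseCountTable(df)


def write_basecount_table(table: BaseCountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_gff3_genes(path) -> list[GeneModel]:
    """Parse gene models from GFF3; exons come from the longest mRNA.

    "Longest" means largest summed exon length; ties break on mRNA ID so the
    choice is deterministic.  An mRNA with no exon features contributes its
    own span as a single exon.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best: tuple[int, str, tuple[tuple[int, int], ...]] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            ) or [(mrna.start, mrna.end)]
            length = sum(e - s + 1 for s, e in exons)
            cand = (length, mrna.id, tuple(exons))
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        exons = best[2] if best else ((gene.start, gene.end),)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand or ".",
                exons=exons,
            )
        )
    return genes


def read_fpkm_table(path) -> pd.DataFrame:
    """Read the FPKM TSV: gene_id, line_id, fpkm, conf_lo, conf_hi.

    Enforces 0 <= conf_lo <= fpkm <= conf_hi; conf_lo may equal 0 (the
    not-expressed signature).
    """
    df = _read_tsv(path, ("gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"))
    for col in ("fpkm", "conf_lo", "conf_hi"):
        df[col] = df[col].astype(float)
    bad = ~(
        (df["conf_lo"] >= 0) & (df["conf_lo"] <= df["fpkm"]) & (df["fpkm"] <= df["conf_hi"])
    )
    if bad.any():
        r = df[bad].iloc[0]
        raise ValidationError(
            f"{r.gene_id}/{r.line_id}: need 0 <= conf_lo <= fpkm <= conf_hi, got "
            f"({r.conf_lo}, {r.fpkm}, {r.conf_hi})"
        )
    return df


def write_fpkm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"])


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=UNCONF,Number=.,Type=String,Description="Lines whose call failed two-line confirmation">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(
    matrix: GenotypeMatrix,
    path,
    *,
    reference: Mapping[tuple[str, int], str] | None = None,
) -> None:
    """Write the genotype matrix as VCFv4.2.

    REF is the reference nucleotide when provided, else the major allele
    (most common call, ties by base order).  Remaining confirmed alleles
    become ALT.  Calls are emitted in the homozygous-inbred convention
    ("0/0", "1/1", ...); MISSING renders "./.".
    """
    loci = matrix.loci
    coords = list(zip(loci["chrom"], loci["pos"]))
    if coords != sorted(coords):
        raise ValidationError("loci must be sorted by (chrom, pos)")
    lines = matrix.lines
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(lines)
            + "\n"
        )
        for i in range(len(loci)):
            chrom, pos = coords[i]
            alleles = list(loci["confirmed_alleles"].iloc[i])
            if len(alleles) < 2:
                raise ValidationError(f"{chrom}:{pos}: fewer than two confirmed alleles")
            if any(a not in BASES for a in alleles):
                raise ValidationError(f"{chrom}:{pos}: allele not in {{A,C,G,T}}")
            row = matrix.calls.iloc[i]
            if reference is not None and (chrom, int(pos)) in reference:
                ref = reference[(chrom, int(pos))]
                if ref not in BASES:
                    raise ValidationError(f"{chrom}:{pos}: reference allele {ref!r} invalid")
            else:
                tally = row[row != MISSING].value_counts()
                in_conf = [a for a in tally.index if a in alleles]
                ref = min(
                    in_conf or alleles,
                    key=lambda a: (-tally.get(a, 0), BASES.index(a)),
                )
            alts = [a for a in alleles if a != ref]
            order = [ref] + alts
            gts = []
            for line in lines:
                a = row[line]
                if a == MISSING or a not in order:
                    gts.append("./.")
                else:
                    k = order.index(a)
                    gts.append(f"{k}/{k}")
            unconf = [
                line for line in lines if matrix.unconfirmed.iloc[i][line]
            ]
            info = f"UNCONF={','.join(unconf)}" if unconf else "."
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read back a VCF written by :func:`write_vcf`."""
    loci_rows = []
    call_rows = []
    lines: list[str] = []
    with Path(path).open() as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if raw.startswith("#CHROM"):
                lines = fields[9:]
                continue
            chrom, pos, _id, ref, alt = fields[:5]
            order = [ref] + (alt.split(",") if alt and alt != "." else [])
            calls = []
            for gt in fields[9:]:
                if gt.startswith("."):
                    calls.append(MISSING)
                else:
                    calls.append(order[int(gt.split("/")[0])])
            loci_rows.append((chrom, int(pos), tuple(sorted(order, key=BASES.index))))
            call_rows.append(calls)
    loci = pd.DataFrame(loci_rows, columns=["chrom", "pos", "confirmed_alleles"])
    calls = pd.DataFrame(call_rows, columns=lines)
    return GenotypeMatrix(loci, calls)


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: skbio.TreeNode, path) -> None:
    """Write a tree as Newick with branch lengths; duplicate leaves rejected."""
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels")
    tree.write(str(path), format="newick")


def read_newick(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# Small auxiliary tables

def read_line_groups(path) -> list[LineGroup]:
    """Read the line->group TSV (columns line_id, group)."""
    df = _read_tsv(path, ("line_id", "group"))
    groups = [LineGroup(r.line_id, r.group) for r in df.itertuples()]
    if len({g.line_id for g in groups}) != len(groups):
        raise ValidationError("duplicate line_id in group map")
    return groups


def write_line_groups(groups: Iterable[LineGroup], path) -> None:
    pd.DataFrame(
        [(g.line_id, g.group) for g in groups], columns=["line_id", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_alignment_summaries(path) -> list[AlignmentSummary]:
    """Read transcript alignment summaries (transcript_id, aligned, coverage,
    identity); coverage/identity are empty for unaligned transcripts."""
    df = _read_tsv(path, ("transcript_id", "aligned", "coverage", "identity"))
    out = []
    for r in df.itertuples():
        aligned = str(r.aligned) in ("1", "True", "true")
        if aligned:
            out.append(AlignmentSummary(r.transcript_id, True, float(r.coverage), float(r.identity)))
        else:
            out.append(AlignmentSummary(r.transcript_id, False))
    return out


def write_alignment_summaries(summaries: Iterable[AlignmentSummary], path) -> None:
    rows = [
        (
            s.transcript_id,
            int(s.aligned),
            "" if s.coverage is None else s.coverage,
            "" if s.identity is None else s.identity,
        )
        for s in summaries
    ]
    pd.DataFrame(rows, columns=["transcript_id", "aligned", "coverage", "identity"]).to_csv(
        path, sep="\t", index=False
    )


def read_read_support(path) -> pd.DataFrame:
    """Read per-transcript, per-line unique/multi-mapped read counts."""
    df = _read_tsv(path, ("transcript_id", "line_id", "unique_reads", "multi_reads"))
    for col in ("unique_reads", "multi_reads"):
        df[col] = df[col].astype(np.int64)
        if (df[col] < 0).any():
            raise ValidationError(f"negative {col}")
    return df


def write_read_support(df: pd.DataFrame, path) -> None:
    df.to_csv(
        path, sep="\t", index=False,
        columns=["transcript_id", "line_id", "unique_reads", "multi_reads"],
    )
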