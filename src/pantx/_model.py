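"""Shared domain containers used across the pipeline.

The public modules (:mod:`pantx.formats_io`, :mod:`pantx.snp_calling`, ...)
re-export these under the names their interfaces document; this module only
exists to keep the import graph acyclic.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical nucleotide order used for every count vector in the pipeline.
BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: Sentinel for a genotype that could not be called.
MISSING: str = "."

#: Fixed vocabulary of pedigree / heterotic groups.
GROUPS: frozenset[str] = frozenset({"SSS", "NSS", "Iodent", "Exotic", "Other"})

BASECOUNT_COLUMNS = ("line_id", "chrom", "pos", "count_A", "count_C", "count_G", "count_T")


class PantxError(Exception):
    """Base class for pipeline errors."""


class ValidationError(PantxError):
    """Input violated a documented contract."""


class ParseError(PantxError):
    """A file could not be parsed; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with the exon structure of its longest annotated mRNA.

    Coordinates are 1-based inclusive throughout (GFF3 convention).
    Strand is recorded for provenance only; all counting is strand-free.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"gene {self.gene_id}: exon {s}-{e} inverted")
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap or unsorted at {s}")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        """Summed exon length; the denominator of per-100-bp SNP density."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class LineGroup:
    """Assignment of an inbred line to its pedigree group."""

    line_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"line {self.line_id}: group {self.group!r} not in {sorted(GROUPS)}"
            )


class BaseCountTable:
    """Per-line, per-position counts of Phred-passing reads for A/C/G/T.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``line_id, chrom, pos, count_A, count_C, count_G, count_T`` and at most
    one row per (line_id, chrom, pos).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in BASECOUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"base-count table missing columns: {missing}")
        df = df.loc[:, list(BASECOUNT_COLUMNS)].reset_index(drop=True)
        counts = df[[f"count_{b}" for b in BASES]]
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative base count")
        if (df["pos"] < 1).any():
            raise ValidationError("positions must be >= 1")
        if df.duplicated(["line_id", "chrom", "pos"]).any():
            dup = df[df.duplicated(["line_id", "chrom", "pos"])].iloc[0]
            raise ValidationError(
                f"duplicate record for ({dup.line_id}, {dup.chrom}, {dup.pos})"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BaseCountTable):
            return NotImplemented
        a = self.df.sort_values(["line_id", "chrom", "pos"]).reset_index(drop=True)
        b = other.df.sort_values(["line_id", "chrom", "pos"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line_id"].unique())

    def pivot(self, lines: Sequence[str] | None = None):
        """Return (loci, counts) with ``loci`` a (chrom, pos) DataFrame sorted
        by coordinate and ``counts`` an int array (n_loci, n_lines, 4); a line
        with no record at a position contributes all-zero counts."""
        lines = list(lines) if lines is not None else self.lines
        line_idx = {l: i for i, l in enumerate(lines)}
        df = self.df[self.df["line_id"].isin(line_idx)]
        loci = (
            df[["chrom", "pos"]].drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
        )
        loc_key = {(c, p): i for i, (c, p) in enumerate(zip(loci["chrom"], loci["pos"]))}
        counts = np.zeros((len(loci), len(lines), 4), dtype=np.int64)
        li = df["line_id"].map(line_idx).to_numpy()
        pi = [loc_key[(c, p)] for c, p in zip(df["chrom"], df["pos"])]
        counts[pi, li, :] = df[[f"count_{b}" for b in BASES]].to_numpy()
        return loci, counts


@dataclass(frozen=True)
class GenotypeCall:
    """A single line's genotype at one position under the 5%/2-read rule."""

    line_id: str
    chrom: str
    pos: int
    allele: str  # one of BASES or MISSING
    passing_alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.allele != MISSING:
            if len(self.passing_alleles) != 1 or self.allele not in self.passing_alleles:
                raise ValidationError("non-missing call requires exactly one passing allele")


class GenotypeMatrix:
    """SNP loci x lines single-nucleotide calls with MISSING entries.

    ``loci`` is a DataFrame with columns chrom, pos, confirmed_alleles (a
    tuple of nucleotides each supported by >= 2 lines); ``calls`` is a
    (n_loci, n_lines) DataFrame of nucleotide strings or MISSING;
    ``unconfirmed`` flags entries whose allele failed the two-line
    confirmation (the call is retained, the flag records it).
    """

    def __init__(
        self,
        loci: pd.DataFrame,
        calls: pd.DataFrame,
        unconfirmed: pd.DataFrame | None = None,
    ):
        if list(calls.index) != list(loci.index):
            calls = calls.reset_index(drop=True)
            loci = loci.reset_index(drop=True)
        self.loci = loci
        self.calls = calls
        if unconfirmed is None:
            unconfirmed = pd.DataFrame(
                False, index=calls.index, columns=calls.columns
            )
        self.unconfirmed = unconfirmed

    @property
    def lines(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_calls(self) -> pd.DataFrame:
        """Tidy export of non-missing calls: chrom, pos, line_id, allele."""
        long = self.calls.copy()
        long["chrom"] = self.loci["chrom"].to_numpy()
        long["pos"] = self.loci["pos"].to_numpy()
        long = long.melt(id_vars=["chrom", "pos"], var_name="line_id", value_name="allele")
        return long[long["allele"] != MISSING].reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci[["chrom", "pos", "confirmed_alleles"]].equals(
                other.loci[["chrom", "pos", "confirmed_alleles"]]
            )
            and self.calls.equals(other.calls)
        )


@dataclass(frozen=True)
class FPKMRecord:
    """Cufflinks-style expression estimate with a 95% confidence interval."""

    gene_id: str
    line_id: str
    fpkm: float
    conf_lo: float
    conf_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.conf_lo <= self.fpkm <= self.conf_hi):
            raise ValidationError(
                f"{self.gene_id}/{self.line_id}: require 0 <= conf_lo <= fpkm <= conf_hi, "
                f"got ({self.conf_lo}, {self.fpkm}, {self.conf_hi})"
            )


class ExpressionCategory(enum.Enum):
    """Semi-quantitative expression bin (FPKM 5 / 200 boundaries)."""

    NONE = "none"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class AlignmentSummary:
    """Best alignment of an assembled transcript against the reference."""

    transcript_id: str
    aligned: bool
    coverage: float | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.aligned:
            if self.coverage is None or self.identity is None:
                raise ValidationError(f"{self.transcript_id}: aligned but no coverage/identity")
            if not (0 <= self.coverage <= 1 and 0 <= self.identity <= 1):
                raise ValidationError(
                    f"{self.transcript_id}: coverage/identity outside [0,1]"
                )
        else:
            if self.coverage is not None or self.identity is not None:
                raise ValidationError(
                    f"{self.transcript_id}: unaligned transcript carries coverage/identity"
                )


class PAVCategory(enum.Enum):
    """Presence/absence class of a transcript across the panel."""

    CORE = "core"
    DISPENSABLE = "dispensable"
    NO_UNIQUE_SUPPORT = "no_unique_support"


def fpkm_frame(records: Iterable[FPKMRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise FPKM input (records or DataFrame) to a validated DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [(r.gene_id, r.line_id, r.fpkm, r.conf_lo, r.conf_hi) for r in records],
            columns=["gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"],
        )
    need = {"gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"}
    if not need <= set(df.columns):
        raise ValidationError(f"FPKM frame needs columns {sorted(need)}")
    bad = ~(
        (df["conf_lo"] >= 0)
        & (df["conf_lo"] <= df["fpkm"])
        & (df["fpkm"] <= df["conf_hi"])
    )
    if bad.any():
        r = df[bad].iloc[0]
        raise ValidationError(
            f"{r.gene_id}/{r.line_id}: require 0 <= conf_lo <= fpkm <= conf_hi"
        )
    return df
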