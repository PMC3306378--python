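"""Genotyping-by-sequencing: barcode demultiplexing and majority-rule calls.

GBS libraries multiplex many lines in one lane with inline barcodes that
abut the ApeKI restriction site.  Demultiplexing here is intentionally
strict: a read is assigned only on a perfect barcode match immediately
followed by a valid cut-site remnant (GCAGC or GCTGC, the two resolutions
of GC[A/T]GC); everything else is discarded and counted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._model import BASES, MISSING, BaseCountTable, ValidationError

__all__ = ["BarcodeMap", "GBSCall", "demultiplex", "call_gbs_genotype", "call_gbs_table"]

#: The two literal 5' remnants of an ApeKI cut site, GC[A/T]GC.
CUT_SITES = ("GCAGC", "GCTGC")

DEFAULT_MIN_MAJORITY = 0.70


class BarcodeMap:
    """Barcode sequence -> line_id, validated unique and prefix-free.

    With perfect-match parsing a barcode that is a prefix of another would
    make assignment ambiguous, so such maps are rejected at load.
    """

    def __init__(self, barcodes: Mapping[str, str]):
        bcs = list(barcodes)
        if len(set(bcs)) != len(bcs):
            raise ValidationError("duplicate barcode")
        for b in bcs:
            if not b or set(b) - set(BASES):
                raise ValidationError(f"invalid barcode {b!r}")
        for a in bcs:
            for b in bcs:
                if a != b and b.startswith(a):
                    raise ValidationError(f"barcode {a!r} is a prefix of {b!r}")
        self._map = dict(barcodes)

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class GBSCall:
    line_id: str
    chrom: str
    pos: int
    allele: str

    def __post_init__(self) -> None:
        if self.allele != MISSING and self.allele not in BASES:
            raise ValidationError(f"allele {self.allele!r} not a nucleotide")


def demultiplex(
    reads: Iterable[tuple[str, str]],
    barcodes: BarcodeMap,
    *,
    keep_cut_site: bool = True,
) -> tuple[dict[str, list[tuple[str, str]]], int]:
    """Assign reads to lines by exact barcode + ApeKI cut-site match.

    A read is kept iff it starts with a barcode immediately followed by
    GCAGC or GCTGC.  The barcode is removed; the cut-site bases are retained
    by default (configurable).  Returns (line_id -> [(read_id, trimmed)],
    n_discarded).
    """
    by_line: dict[str, list[tuple[str, str]]] = {line: [] for _, line in barcodes.items()}
    discarded = 0
    items = list(barcodes.items())
    for read_id, seq in reads:
        hit = None
        for bc, line in items:
            if seq.startswith(bc) and seq[len(bc):len(bc) + 5] in CUT_SITES:
                hit = (bc, line)
                break
        if hit is None:
            discarded += 1
            continue
        bc, line = hit
        start = len(bc) if keep_cut_site else len(bc) + 5
        by_line[line].append((read_id, seq[start:]))
    return by_line, discarded


def call_gbs_genotype(
    counts: Sequence[int],
    *,
    min_majority: float = DEFAULT_MIN_MAJORITY,
) -> str:
    """Majority-rule genotype from (A, C, G, T) counts.

    Returns the nucleotide holding at least ``min_majority`` (default 70%)
    of the reads, else MISSING; zero total reads is MISSING.  Above 50%
    the winner is unique, so no tie-break is needed.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (4,):
        raise ValidationError("expected four counts (A, C, G, T)")
    if (counts < 0).any():
        raise ValidationError("negative count")
    total = counts.sum()
    if total == 0:
        return MISSING
    best = int(counts.argmax())
    if counts[best] >= min_majority * total:
        return BASES[best]
    return MISSING


def call_gbs_table(
    table: BaseCountTable,
    *,
    min_majority: float = DEFAULT_MIN_MAJORITY,
) -> pd.DataFrame:
    """Vectorised 70%-rule calls for a whole GBS count table.

    Returns tidy non-missing calls: chrom, pos, line_id, allele.
    """
    df = table.df
    counts = df[[f"count_{b}" for b in BASES]].to_numpy()
    total = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    ok = (total > 0) & (counts[np.arange(len(df)), best] >= min_majority * total)
    out = df.loc[ok, ["chrom", "pos", "line_id"]].copy()
    out["allele"] = np.array(BASES)[best[ok]]
    return out.reset_index(drop=True)
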