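"""Agreement between genotype call sets and against a reference sequence.

Calls are compared as data points — one (chromosome, position, line) cell
with a non-missing nucleotide — so two methods are scored only where both
made a call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._model import MISSING, PantxError

__all__ = [
    "UndefinedRateError",
    "ReferenceConcordance",
    "CrossMethodConcordance",
    "reference_concordance",
    "cross_method_concordance",
]

_CALL_COLS = ["chrom", "pos", "line_id", "allele"]


class UndefinedRateError(PantxError):
    """Raised when a concordance rate has an empty denominator."""


@dataclass(frozen=True)
class ReferenceConcordance:
    n_compared: int
    n_matching: int
    rate: float
    n_absent_from_reference: int


@dataclass(frozen=True)
class CrossMethodConcordance:
    n_shared_points: int
    n_concordant: int
    rate: float
    contradiction_positions: tuple[tuple[str, int], ...]
    n_positions: int


def _check_calls(calls: pd.DataFrame) -> pd.DataFrame:
    if not set(_CALL_COLS) <= set(calls.columns):
        raise ValueError(f"call frame needs columns {_CALL_COLS}")
    return calls[calls["allele"] != MISSING]


def reference_concordance(
    calls: pd.DataFrame,
    reference: Mapping[tuple[str, int], str],
) -> ReferenceConcordance:
    """Fraction of called data points matching the reference nucleotide.

    Positions absent from the reference map are excluded from the rate and
    counted separately.  An empty comparison set raises
    :class:`UndefinedRateError`.
    """
    calls = _check_calls(calls)
    n_absent = 0
    n_compared = 0
    n_match = 0
    for chrom, pos, allele in zip(calls["chrom"], calls["pos"], calls["allele"]):
        ref = reference.get((chrom, int(pos)))
        if ref is None:
            n_absent += 1
            continue
        n_compared += 1
        n_match += allele == ref
    if n_compared == 0:
        raise UndefinedRateError("no call positions present in reference")
    return ReferenceConcordance(n_compared, n_match, n_match / n_compared, n_absent)


def cross_method_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    *,
    max_contradicting_lines: int = 2,
) -> CrossMethodConcordance:
    """Agreement between two call sets over shared (position, line) points.

    A point is shared when both methods made a non-missing call for the same
    line at the same coordinate; it is concordant when the nucleotides are
    equal.  A position is flagged contradictory when more than
    ``max_contradicting_lines`` lines disagree between the methods there.
    The measure is symmetric in its arguments.
    """
    a = _check_calls(a)
    b = _check_calls(b)
    merged = a.merge(
        b, on=["chrom", "pos", "line_id"], suffixes=("_a", "_b"), how="inner"
    )
    n_shared = len(merged)
    if n_shared == 0:
        raise UndefinedRateError("no shared data points")
    agree = merged["allele_a"] == merged["allele_b"]
    n_conc = int(agree.sum())
    disagreements = merged[~agree].groupby(["chrom", "pos"])["line_id"].nunique()
    contradictions = tuple(
        sorted(
            (chrom, int(pos))
            for (chrom, pos), n in disagreements.items()
            if n > max_contradicting_lines
        )
    )
    n_positions = merged.groupby(["chrom", "pos"]).ngroups
    return CrossMethodConcordance(
        n_shared, n_conc, n_conc / n_shared, contradictions, n_positions
    )
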