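"""Independent brute-force re-statements of the pipeline rules.

These are deliberately naive dict-and-loop implementations, kept free of
any code from :mod:`pantx`'s vectorised paths, so they can serve as
oracles for randomized equivalence tests.
"""
from __future__ import annotations

import math
from collections import Counter

BASES = ("A", "C", "G", "T")
MISSING = "."


def brute_call(counts, min_reads=2, min_frac=0.05):
    """Per-line genotype rule, restated: >= min_reads reads and strictly
    more than min_frac of the total."""
    total = sum(counts)
    passing = {
        BASES[i]
        for i in range(4)
        if counts[i] >= min_reads and counts[i] > min_frac * total
    }
    allele = next(iter(passing)) if len(passing) == 1 else MISSING
    return allele, passing


def brute_discover(records, lines, min_reads=2, min_frac=0.05, min_lines=2, min_alleles=2):
    """Full SNP discovery restated.

    ``records`` maps (line_id, chrom, pos) -> (nA, nC, nG, nT).  Returns a
    list of (chrom, pos, confirmed_alleles_sorted, calls_in_line_order).
    """
    positions = sorted({(c, p) for (_, c, p) in records})
    loci = []
    for chrom, pos in positions:
        calls = {
            line: brute_call(records.get((line, chrom, pos), (0, 0, 0, 0)), min_reads, min_frac)[0]
            for line in lines
        }
        tally = Counter(a for a in calls.values() if a != MISSING)
        confirmed = tuple(sorted((a for a, n in tally.items() if n >= min_lines),
                                 key=BASES.index))
        if len(confirmed) >= min_alleles:
            loci.append((chrom, pos, confirmed, [calls[l] for l in lines]))
    return loci


def brute_gbs_call(counts, min_majority=0.70):
    total = sum(counts)
    if total == 0:
        return MISSING
    for i in range(4):
        if counts[i] / total >= min_majority:
            return BASES[i]
    return MISSING


def brute_cross_concordance(a, b, max_contradicting=2):
    """``a``/``b`` map (chrom, pos, line) -> allele (non-missing only)."""
    shared = set(a) & set(b)
    n_conc = sum(1 for k in shared if a[k] == b[k])
    lines_disagreeing = {}
    for chrom, pos, line in shared:
        if a[(chrom, pos, line)] != b[(chrom, pos, line)]:
            lines_disagreeing.setdefault((chrom, pos), set()).add(line)
    contradictions = sorted(
        k for k, ls in lines_disagreeing.items() if len(ls) > max_contradicting
    )
    return len(shared), n_conc, contradictions


def brute_reference_concordance(calls, reference):
    """``calls`` is a list of (chrom, pos, line, allele)."""
    n_comp = n_match = n_absent = 0
    for chrom, pos, _line, allele in calls:
        if (chrom, pos) not in reference:
            n_absent += 1
            continue
        n_comp += 1
        n_match += reference[(chrom, pos)] == allele
    return n_comp, n_match, n_absent


def brute_rogers(g1, g2):
    """Frequency-based Rogers distance: per locus sqrt(0.5 * sum (p-q)^2)
    with 0/1 indicator frequencies, averaged over pairwise-complete loci."""
    total = 0.0
    n = 0
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        p = [1.0 if base == a else 0.0 for base in BASES]
        q = [1.0 if base == b else 0.0 for base in BASES]
        total += math.sqrt(0.5 * sum((x - y) ** 2 for x, y in zip(p, q)))
        n += 1
    return total / n if n else None


def brute_filter(summaries, cov_cut=0.85, id_cut=0.85):
    """``summaries``: list of (transcript_id, aligned, coverage, identity)."""
    retained, n_un, n_below, n_removed = [], 0, 0, 0
    for tid, aligned, cov, ident in summaries:
        if not aligned:
            n_un += 1
            retained.append(tid)
        elif cov > cov_cut and ident > id_cut:
            n_removed += 1
        else:
            n_below += 1
            retained.append(tid)
    return retained, n_un, n_below, n_removed


def brute_classify(support, n_lines, mode="unique"):
    """``support``: dict (transcript, line) -> (unique, multi).  Returns
    transcript -> (n_lines_supported, category string)."""
    per_tx = {}
    for (tid, _line), (u, m) in support.items():
        reads = u if mode == "unique" else u + m
        per_tx[tid] = per_tx.get(tid, 0) + (1 if reads >= 1 else 0)
    out = {}
    for tid, n in per_tx.items():
        if n == n_lines:
            cat = "core"
        elif n > 0:
            cat = "dispensable"
        else:
            cat = "no_unique_support"
        out[tid] = (n, cat)
    return out


def brute_group_sets(presence, group_of, mode="all_groups", pair=None):
    """``presence``: dict transcript -> set of lines where present."""
    if mode == "pairwise":
        lines_kept = {l for l, g in group_of.items() if g in pair}
        groups = list(pair)
    else:
        lines_kept = set(group_of)
        groups = sorted({g for g in group_of.values()})
    out = {g: set() for g in groups}
    if mode == "pairwise":
        out["shared"] = set()
    for tid, lines in presence.items():
        gs = {group_of[l] for l in lines & lines_kept}
        if len(gs) == 1:
            out[next(iter(gs))].add(tid)
        elif mode == "pairwise" and len(gs) == 2:
            out["shared"].add(tid)
    return out
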