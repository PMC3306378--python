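#!/usr/bin/env python
"""Filter assembled transcripts for novelty and analyse presence/absence.

Transcripts whose best reference alignment exceeds 85% coverage AND 85%
identity are removed as alleles/paralogs of annotated sequence; the
coverage/identity cutoff sweep (70-95%) documents that operating point.
Retained transcripts are classified CORE / DISPENSABLE / NO_UNIQUE_SUPPORT
from unique-read support, and group-specific sets are computed over all
pedigree groups and for the SSS vs NSS heterotic-group contrast.
"""
from pathlib import Path

from pantx import formats_io as io
from pantx import novel_pav as pav
from pantx._model import PAVCategory

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    summaries = io.read_alignment_summaries(STUDY / "alignments.tsv")
    res = pav.filter_novel(summaries)
    print(f"{len(res.retained)} of {len(summaries)} transcripts retained as novel "
          f"({res.n_unaligned} never aligned, {res.n_below_cutoff} below cutoff, "
          f"{res.n_removed} removed)")
    (OUT / "novel_retained_ids.txt").write_text("\n".join(res.retained) + "\n")
    pav.cutoff_sweep(summaries).to_csv(OUT / "novel_cutoff_sweep.tsv", sep="\t", index=False)

    support = io.read_read_support(STUDY / "read_support.tsv")
    support = support[support["transcript_id"].isin(res.retained)]
    n_lines = support["line_id"].nunique()
    classes = pav.classify_support(support, n_lines, mode="unique")
    classes.assign(category=classes["category"].map(lambda c: c.value)).to_csv(
        OUT / "novel_pav_classes.tsv", sep="\t", index=False
    )
    counts = classes["category"].value_counts()
    print(f"unique-read support: {counts.get(PAVCategory.CORE, 0)} core, "
          f"{counts.get(PAVCategory.DISPENSABLE, 0)} dispensable, "
          f"{counts.get(PAVCategory.NO_UNIQUE_SUPPORT, 0)} without unique support")
    multi = pav.classify_support(support, n_lines, mode="multi")
    print(f"allowing multi-mapped reads, "
          f"{(multi['n_lines_supported'] > 0).sum()} of {len(multi)} have support")

    groups = io.read_line_groups(STUDY / "line_groups.tsv")
    presence = (
        support.assign(_p=support["unique_reads"] >= 1)
        .pivot(index="transcript_id", columns="line_id", values="_p")
        .fillna(False)
    )
    sets = pav.group_specific_sets(presence, groups)
    with (OUT / "novel_group_sets.tsv").open("w") as fh:
        fh.write("comparison\tgroup\tn_transcripts\n")
        for g, ids in sorted(sets.items()):
            fh.write(f"all_groups\t{g}\t{len(ids)}\n")
        pair = pav.group_specific_sets(presence, groups, comparison="pairwise", pair=("SSS", "NSS"))
        for g, ids in sorted(pair.items()):
            fh.write(f"SSS_vs_NSS\t{g}\t{len(ids)}\n")
    n_spec = sum(len(s) for s in sets.values())
    print(f"{n_spec} transcripts specific to a single pedigree group; "
          f"SSS/NSS contrast: {len(pair['SSS'])} SSS-only, {len(pair['NSS'])} NSS-only, "
          f"{len(pair['shared'])} shared")


if __name__ == "__main__":
    main()
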