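#!/usr/bin/env python
"""Simulate the miniature 21-line study that drives the rest of the analysis.

Writes every pipeline input (base counts, GBS counts, FPKM table, alignment
summaries, read support, line groups, gene models) plus the ground-truth
tables to results/study/, using the default study design: 21 lines in five
pedigree groups (3 SSS, 8 NSS, 1 Iodent, 5 Exotic, 4 Other), 3,000 exonic
SNPs (30% group-private), 3,000 invariant sites, mean depth 20x, 0.5%
per-base error, and 250 assembled transcripts of which 150 are truly novel.
"""
import sys
from pathlib import Path

from pantx import formats_io as io
from pantx import synthetic_data as sim

OUT = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    config = sim.SimulationConfig(seed=SEED)
    study = sim.simulate_study(config)
    truth = study["truth"]
    OUT.mkdir(parents=True, exist_ok=True)

    io.write_basecount_table(study["basecounts"], OUT / "basecounts.tsv")
    io.write_basecount_table(study["gbs_counts"], OUT / "gbs_counts.tsv")
    io.write_fpkm_table(study["fpkm"], OUT / "fpkm.tsv")
    io.write_alignment_summaries(study["alignments"], OUT / "alignments.tsv")
    io.write_read_support(study["read_support"], OUT / "read_support.tsv")
    io.write_line_groups(truth.line_groups, OUT / "line_groups.tsv")
    truth.snp_loci.to_csv(OUT / "truth_snps.tsv", sep="\t", index=False)
    truth.invariant_loci.to_csv(OUT / "truth_invariant.tsv", sep="\t", index=False)
    import pandas as pd

    geno = pd.DataFrame(truth.genotypes, columns=list(truth.lines))
    geno.insert(0, "chrom", truth.snp_loci["chrom"])
    geno.insert(1, "pos", truth.snp_loci["pos"])
    geno.to_csv(OUT / "truth_genotypes.tsv", sep="\t", index=False)
    truth.novel_presence.to_csv(OUT / "truth_novel_presence.tsv", sep="\t")
    with (OUT / "genes.gff3").open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}.t1\n")

    print(f"panel: {len(truth.lines)} lines, {len(truth.genes)} genes, "
          f"{len(truth.snp_loci)} true SNPs, {len(truth.novel_ids)} novel transcripts")
    print(f"inputs and truth written to {OUT}/ (seed {SEED})")


if __name__ == "__main__":
    main()
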