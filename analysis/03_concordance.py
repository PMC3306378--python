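#!/usr/bin/env python
"""Check the RNA-seq SNP calls against the independent GBS genotypes.

GBS counts are called under the 70% majority rule, then compared with the
RNA-seq genotype matrix over shared (position, line) data points; positions
where more than two lines contradict are flagged.  Both call sets are also
scored against the simulated reference (truth) alleles.
"""
from pathlib import Path

import pandas as pd

from pantx import concordance as conc
from pantx import formats_io as io
from pantx import gbs_genotyping as gbs
from pantx import snp_calling as snp

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    matrix = io.read_vcf(OUT / "snps.vcf")
    rna_calls = matrix.to_calls()
    gbs_table = io.read_basecount_table(STUDY / "gbs_counts.tsv")
    gbs_calls = gbs.call_gbs_table(gbs_table)

    res = conc.cross_method_concordance(rna_calls, gbs_calls)
    print(f"{res.n_shared_points} shared data points over {res.n_positions} positions")
    print(f"cross-method concordance {100 * res.rate:.2f}% "
          f"({res.n_concordant} concordant)")
    print(f"{len(res.contradiction_positions)} positions with >2 contradicting lines")

    # error-rate check, mirroring a reference line compared to its own
    # genome: one line's calls at ALL covered sites (mostly monomorphic)
    # against that line's true alleles
    geno = pd.read_csv(STUDY / "truth_genotypes.tsv", sep="\t")
    invariant = pd.read_csv(STUDY / "truth_invariant.tsv", sep="\t")
    ref_line = [c for c in geno.columns if c not in ("chrom", "pos")][0]
    reference = {(r.chrom, r.pos): getattr(r, ref_line) for r in geno.itertuples()}
    reference |= {(r.chrom, r.pos): r.ref for r in invariant.itertuples()}
    rna_table = io.read_basecount_table(STUDY / "basecounts.tsv")
    own_calls = snp.call_genotypes_table(rna_table)
    own_calls = own_calls[own_calls["line_id"] == ref_line]
    r = conc.reference_concordance(own_calls, reference)
    print(f"{ref_line} vs its own reference genome: {100 * r.rate:.2f}% of "
          f"{r.n_compared} all-site calls concordant")
    pd.DataFrame(
        [(f"{ref_line}_all_sites", r.n_compared, r.n_matching, r.rate, r.n_absent_from_reference)],
        columns=["method", "n_compared", "n_matching", "rate", "n_absent"],
    ).to_csv(OUT / "reference_concordance.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(res.n_shared_points, res.n_concordant, res.rate, len(res.contradiction_positions))],
        columns=["n_shared_points", "n_concordant", "rate", "n_contradictory_positions"],
    ).to_csv(OUT / "cross_method_concordance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
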