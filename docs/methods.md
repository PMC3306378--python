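# Methods

This note documents the models and procedures implemented in `pantx`, the
parameters that matter, the synthetic data they are exercised on, and the
numerical and design choices made where a convention had to be picked.

## SNP calling from base-count pileups

The caller's sole input is a table of per-line, per-position counts of
quality-filtered reads for A/C/G/T (`BaseCountTable`). Upstream alignment
and Phred filtering are out of scope by contract: the counts are assumed to
contain only reads passing the quality filter.

Three rules are applied in sequence:

1. **Per-line genotype.** A nucleotide passes for a line iff its count is
   ≥ `min_reads` (default 2) and strictly greater than `min_frac` (default
   0.05) of the line's total filtered reads at the position. The
   denominator of the fraction rule is the sum of the four post-filter base
   counts — no separate raw-depth denominator exists in the data model.
   Exactly one passing nucleotide is the call; zero (including zero
   coverage) or two or more passing nucleotides give MISSING. A
   multi-allele signal in a (near-)homozygous inbred cannot be
   distinguished from a collapsed duplication with divergent copies, so it
   is treated as missing data rather than heterozygosity.
2. **Allele confirmation.** An allele exists at a position only if ≥
   `min_lines` (default 2) lines carry it as their single call.
3. **SNP emission.** A position is emitted iff ≥ `min_alleles` (default 2)
   confirmed alleles remain. A consequence asserted in the tests: every
   emitted locus has non-missing calls in ≥ 4 lines.

Boundary semantics are deliberate: the fraction rule is strict (2 of 40
reads is exactly 5% and fails), the read-count rule is inclusive (2 reads
suffice). Three or more confirmed alleles yield one multi-allelic locus
(several ALT alleles in VCF), not split records. Per-line calls that fail
confirmation at an emitted locus are retained in the matrix and flagged
`unconfirmed` — the confirmation rule gates locus emission, not individual
calls; the flag lets downstream consumers mask them if they prefer the
stricter reading.

Derived statistics: per-gene SNP counts assign a locus to every gene whose
exon set contains its position (RNA-seq reads are exonic; gene-span
containment is available via `by="span"`); density divides by the summed
exon length of the longest annotated mRNA, per 100 bp. Window densities bin
SNPs by position and genes by midpoint into fixed windows (default 1 Mb;
the analysis scripts use 50 kb to suit the miniature genome); a gene counts
as expressed in a window when ≥ 4 lines have a positive FPKM-CI lower
bound, four being the minimum number of informative lines for a SNP call.

## GBS genotyping

Demultiplexing keeps a read iff it begins with an exact barcode match
immediately followed by one of the two ApeKI cut-site remnants `GCAGC` /
`GCTGC`; everything else is counted as discarded. Barcode maps must be
unique and prefix-free — with perfect-match parsing a prefix collision is
ambiguous, so it is rejected at load. Whether the cut-site bases are
retained after barcode trimming is a convention; they are retained by
default and removable with `keep_cut_site=False`. Genotypes are called per
site by simple majority: the nucleotide holding ≥ 70% of reads (inclusive:
7 of 10 reads passes), MISSING otherwise; above 50% the winner is unique so
no tie-break arises.

## Concordance

Two call sets are compared over shared data points — (chromosome, position,
line) cells non-missing in both — and a position is flagged contradictory
when more than two lines disagree there. Rates are kept at full precision
internally; presentation rounds to two decimals. An empty denominator
raises rather than returning NaN. Reference concordance excludes (and
counts) positions absent from the reference map.

## Rogers distance and neighbor joining

Rogers' distance averages per-locus allele-frequency distances
√(½ Σₐ (pₐ − qₐ)²). With homozygous single-nucleotide calls the
frequencies are 0/1 indicators and the per-locus term is 0 or 1, so the
distance is the mismatch proportion over pairwise-complete loci. Loci
missing in either line are deleted pairwise; a pair with fewer than
`min_shared` complete loci (default 100 for panel matrices) is undefined
and aborts with a report naming the offending pairs, rather than silently
producing a noisy estimate. Residual heterozygous calls cannot reach this
module: the caller maps them to MISSING.

Neighbor joining is the standard Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with two-point limb
lengths and the usual distance update. Conventions: Q ties break to the
lowest (row, column) index pair in the current working order, making the
output deterministic; negative limb estimates are clamped to zero with the
deficit transferred to the sister limb (Kuhner–Felsenstein), preserving
the joined pair's distance; the final three subtrees attach to one
trifurcating node by the closed-form three-point formulas (clamp only —
the transfer target is ambiguous there, and additive inputs never need
it). On any matrix exactly additive on a binary tree with positive branch
lengths the source tree is recovered to < 1e-9 in tip-to-tip path length;
the test suite also cross-checks path lengths against scikit-bio's
independent NJ implementation.

Group clustering is scored by a leaf-partition test: a group forms a
connected subtree of the unrooted tree iff some edge bipartitions the
leaves into exactly (group, rest), checked over all edges.

## Expression classification

A gene is expressed in a line iff its 95% FPKM confidence-interval lower
bound is strictly greater than zero. The comparison is exact (no epsilon):
upstream quantification emits literal zeros for unexpressed genes, and the
zero lower bound is that signature. Semi-quantitative bins: NONE when
`conf_lo == 0`; otherwise LOW for FPKM < 5, MEDIUM for 5 ≤ FPKM ≤ 200
(both boundaries inclusive), HIGH for FPKM > 200.

Panel partitions need a complete gene × line matrix; genes absent from a
line's table can be densified to (0, 0, 0) with a warning
(`densify_fpkm`), but the partition functions themselves reject incomplete
input rather than guessing. The histogram of lines-expressed buckets sums
to the gene total; bucket N is the core transcriptome, buckets 1..N−1 the
dispensable transcriptome, bucket 0 the silent set. The per-line summary's
percentage denominator is the annotated gene total — an input property,
defaulting to the number of distinct genes in the table; argmax ties break
to the lexicographically first gene id.

## Novel transcripts and presence/absence

One representative — the longest transcript, ties to the lexicographically
first id — stands for each assembly locus; the assembly's 500 bp minimum
length is enforced at entry. When several alignments reach this module,
the best one is the maximal coverage × identity product, ties to higher
coverage. The novelty filter removes a transcript only when its best
alignment exceeds **both** cutoffs strictly (defaults 0.85/0.85);
retention is the complement — never aligned, or below either cutoff. The
cutoff sweep recomputes removal counts over a 0.70–0.95 grid and is
monotone non-increasing in both arguments; on real data the removal curve
drops sharply past 85%, which is how that operating point is chosen.

Presence of a retained transcript in a line requires ≥ 1 uniquely mapping
read (`unique` mode); `multi` mode also admits multi-mapped reads, which
rescues paralog-like transcripts that can never be hit uniquely.
Transcripts present in all N lines are CORE, in 1..N−1 DISPENSABLE, in
none NO_UNIQUE_SUPPORT. Group-specific sets: a transcript is specific to a
pedigree group iff present in ≥ 1 of its lines and absent from every line
of every other group under consideration; the pairwise (heterotic-group)
mode restricts the line set to the two groups first, so presence in an
outside group does not disqualify. All lines are treated symmetrically,
including any reference line.

## Synthetic data

The generator draws a complete miniature study from one seed. Defaults
mirror the motivating design: 21 lines in groups of 3 SSS / 8 NSS /
1 Iodent / 5 Exotic / 4 Other; 300 three-exon genes (300 bp exons, 200 bp
introns) on two chromosomes; 3,000 exonic SNPs of which 30% are
group-private; 3,000 invariant exonic sites (the substrate for false
discoveries); gene expression classes at 48.7% core / 27.9% variable /
23.4% silent; 250 assembled transcripts of which 150 are truly novel
(28% of them never aligning, the rest below cutoff) and 100 are
reference-like (both alignment figures above 0.85); mean depth 20 reads
per site; per-base error 0.005; 10% CI dropout of lowly expressed cells.
Expressed FPKM values draw uniformly from their bin's range with a CI
strictly bracketing the estimate.

Sequencing counts follow the simplest model that exposes every rule
boundary: depth ~ Poisson(mean_depth) per line × site; each read reports
the true base with probability 1 − error_rate, else a uniformly chosen
other base; counts sum to depth; zero-depth cells are omitted from the
table so the caller must treat them as missing. Every SNP's two alleles
each have ≥ 2 carrier lines, matching the caller's confirmation
requirement; minor-allele carriers of non-private loci always span ≥ 2
groups. Each generation stage draws from a child generator derived from
the global seed by a fixed stage offset, so stages are independently
reproducible and the whole study is deterministic given (config, seed).

What the generator does **not** model — and what passing tests therefore
do not demonstrate about real data: alignment and mapping bias, splice
structure, linkage disequilibrium beyond group-private alleles, residual
heterozygosity, overdispersed depth, quality-score miscalibration,
reference errors, paralog collapse (the mechanism motivating the
missing-data rule appears only as its symptom, the multi-only read-support
class), and contamination. Recovery results on simulated panels bound the
pipeline's correctness, not the error rate of any real experiment.

`evaluate_snp_recovery` scores a called matrix against truth. A true locus
counts as *discoverable* when each allele has ≥ 2 carrier lines whose
reads would pass the per-line thresholds on the true allele; sensitivity
is measured over discoverable loci, the false-discovery proportion over
all emitted loci. On 20 replicate panels of 12 lines / 2,000 SNPs at depth
20 and error 0.005 the suite requires sensitivity ≥ 0.95, FDR ≤ 0.01, and
each pedigree group a connected NJ subtree in ≥ 19 of 20 replicates.

## Problem sizes

The analysis scripts and the acceptance script run the 21-line default
panel (3,000 SNPs + 3,000 invariant sites, 300 genes, 250 transcripts);
the acceptance property suites use panels of 12 lines × 2,000 SNPs × 20
replicates and randomized small instances (≤ 6 lines, ≤ 50 positions) for
oracle equivalence. These sizes exercise every rule boundary while
keeping a full run in seconds.

## Known limitations

- The caller emits loci, not blocks; no indels, no SSRs, no
  allele-specific expression analysis.
- VCF output is a minimal dialect (GT-only, UNCONF info field); it is
  structurally valid VCFv4.2 but carries no quality annotations.
- The GBS module starts from count tables or raw barcoded reads; alignment
  of GBS reads is upstream and out of scope.
- `distance_matrix` is quadratic in lines and linear in loci — adequate
  for panels of tens of lines, not for thousands.
- Bootstrap support, tree rooting and visualisation are intentionally
  absent.
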