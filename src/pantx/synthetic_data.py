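"""Seeded generator for a complete miniature inbred-panel study.

Emulates the statistical structure of a multi-line seedling RNA-seq
experiment: homozygous inbred lines drawn from distinct pedigree groups,
exonic SNP loci whose minor allele is either shared across groups or
private to one, Poisson sequencing depth with uniform substitution errors,
FPKM tables whose confidence-interval lower bound is zero for absent (and
occasionally for lowly sampled) genes, and assembled novel transcripts
with known alignment coverage/identity against the reference and per-line
read support.

Every stage draws from a child generator derived from the single
configured seed by a fixed stage offset, so each stage is independently
reproducible and the whole study is byte-identical given (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._model import (
    BASES,
    MISSING,
    BaseCountTable,
    ExpressionCategory,
    GeneModel,
    LineGroup,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "Truth",
    "simulate_population",
    "simulate_basecounts",
    "simulate_fpkm_table",
    "simulate_alignment_summaries",
    "simulate_read_support",
    "simulate_gbs_counts",
    "simulate_study",
    "evaluate_snp_recovery",
]

# fixed per-stage offsets for fanning the global seed out
_STAGE_POPULATION = 0
_STAGE_BASECOUNTS = 1
_STAGE_FPKM = 2
_STAGE_ALIGNMENT = 3
_STAGE_SUPPORT = 4
_STAGE_GBS = 5

#: Default panel mirrors the 21-line study design: 3 Stiff Stalk Synthetic,
#: 8 Non-Stiff Stalk Synthetic, 1 Iodent, 5 exotic and 4 other lines.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "SSS": 3,
    "NSS": 8,
    "Iodent": 1,
    "Exotic": 5,
    "Other": 4,
}


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the miniature panel.

    The gene-class fractions default to the core/dispensable structure
    observed in diverse maize seedling panels (roughly half of annotated
    genes expressed in every line, a quarter in a proper subset, a quarter
    in none); depth and error defaults correspond to a well-powered RNA-seq
    pileup after quality filtering.
    """

    n_lines: int = 21
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_genes: int = 300
    n_snps: int = 3000
    n_invariant_sites: int = 3000
    group_private_snp_fraction: float = 0.3
    n_novel_transcripts: int = 150
    core_novel_fraction: float = 0.45
    group_private_novel_fraction: float = 0.15
    multi_only_novel_fraction: float = 0.03
    n_reference_like_transcripts: int = 100
    unaligned_novel_fraction: float = 0.28
    gene_absent_fraction: float = 0.234
    gene_core_fraction: float = 0.487
    mean_depth: float = 20.0
    error_rate: float = 0.005
    fpkm_absent_rate: float = 0.1
    support_mean_reads: float = 5.0
    gbs_site_fraction: float = 0.3
    gbs_mean_depth: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "group_private_snp_fraction",
            "core_novel_fraction",
            "group_private_novel_fraction",
            "multi_only_novel_fraction",
            "unaligned_novel_fraction",
            "gene_absent_fraction",
            "gene_core_fraction",
            "error_rate",
            "fpkm_absent_rate",
            "gbs_site_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if self.gene_absent_fraction + self.gene_core_fraction > 1:
            raise ValidationError("gene class fractions exceed 1")
        if sum(self.group_sizes.values()) != self.n_lines:
            raise ValidationError(
                f"group sizes sum to {sum(self.group_sizes.values())}, "
                f"expected n_lines={self.n_lines}"
            )
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.n_lines < 4:
            raise ValidationError("panel needs at least 4 lines for SNP discovery")


@dataclass(frozen=True)
class Truth:
    """Ground truth for one simulated study."""

    lines: tuple[str, ...]
    line_groups: tuple[LineGroup, ...]
    genes: tuple[GeneModel, ...]
    snp_loci: pd.DataFrame  # chrom, pos, ref, alt, private_group (or "")
    genotypes: np.ndarray  # (n_snps, n_lines) nucleotide letters
    invariant_loci: pd.DataFrame  # chrom, pos, ref
    expression: pd.DataFrame  # genes x lines of ExpressionCategory
    novel_ids: tuple[str, ...]
    reference_like_ids: tuple[str, ...]
    novel_lengths: Mapping[str, int]
    novel_presence: pd.DataFrame  # novel transcripts x lines, boolean
    multi_only: frozenset[str]

    def group_members(self, group: str) -> list[str]:
        return [g.line_id for g in self.line_groups if g.group == group]

    @property
    def all_loci(self) -> pd.DataFrame:
        """SNP plus invariant positions with per-line true alleles."""
        inv = self.invariant_loci
        inv_geno = np.tile(inv["ref"].to_numpy()[:, None], (1, len(self.lines)))
        loci = pd.concat(
            [self.snp_loci[["chrom", "pos"]], inv[["chrom", "pos"]]], ignore_index=True
        )
        geno = np.vstack([self.genotypes, inv_geno]) if len(inv) else self.genotypes
        order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
        return loci.iloc[order].reset_index(drop=True), geno[order]


def _make_lines(config: SimulationConfig) -> tuple[tuple[str, ...], tuple[LineGroup, ...]]:
    lines, groups = [], []
    for group, size in config.group_sizes.items():
        for i in range(size):
            lid = f"{group}{i + 1:02d}"
            lines.append(lid)
            groups.append(LineGroup(lid, group))
    return tuple(lines), tuple(groups)


def _make_genes(config: SimulationConfig) -> tuple[GeneModel, ...]:
    """Two chromosomes of evenly spaced three-exon genes (300 bp exons,
    200 bp introns)."""
    genes = []
    per_chrom = math.ceil(config.n_genes / 2)
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        k = i % per_chrom
        start = 1 + k * 2000
        exons = tuple(
            (start + j * 500, start + j * 500 + 299) for j in range(3)
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:05d}",
                chrom=chrom,
                start=start,
                end=exons[-1][1],
                strand="+" if i % 2 == 0 else "-",
                exons=exons,
            )
        )
    return tuple(genes)


def _random_subset(rng: np.random.Generator, items: Sequence, size: int) -> list:
    idx = rng.choice(len(items), size=size, replace=False)
    return [items[i] for i in sorted(idx)]


def simulate_population(config: SimulationConfig) -> Truth:
    """Draw the ground truth: panel, gene models, genotypes, expression,
    novel transcripts.

    SNP loci are placed uniformly within exons.  A
    ``group_private_snp_fraction`` of loci carry their minor allele only in
    lines of one pedigree group; every other locus has minor-allele
    carriers spanning at least two groups.  Each allele of every SNP is
    carried by at least two lines, matching the caller's confirmation
    requirement.  Deterministic given the config seed.
    """
    rng = _stage_rng(config.seed, _STAGE_POPULATION)
    lines, line_groups = _make_lines(config)
    genes = _make_genes(config)

    exonic = [
        (g.chrom, p) for g in genes for s, e in g.exons for p in range(s, e + 1)
    ]
    n_sites = config.n_snps + config.n_invariant_sites
    if n_sites > len(exonic):
        raise ValidationError(
            f"{n_sites} sites requested but only {len(exonic)} exonic positions exist"
        )
    picked = rng.choice(len(exonic), size=n_sites, replace=False)
    snp_sites = sorted(exonic[i] for i in picked[: config.n_snps])
    inv_sites = sorted(exonic[i] for i in picked[config.n_snps:])

    n_lines = len(lines)
    group_of = {g.line_id: g.group for g in line_groups}
    line_idx_by_group = {
        grp: [i for i, l in enumerate(lines) if group_of[l] == grp]
        for grp in config.group_sizes
    }
    private_eligible = [g for g, idx in line_idx_by_group.items() if len(idx) >= 2]
    n_private = round(config.group_private_snp_fraction * config.n_snps)
    if n_private and not private_eligible:
        raise ValidationError("group-private SNPs need a group with >= 2 lines")

    base_codes = rng.integers(0, 4, size=config.n_snps)
    genotypes = np.empty((config.n_snps, n_lines), dtype="U1")
    rows = []
    for s, (chrom, pos) in enumerate(snp_sites):
        ref = BASES[base_codes[s]]
        alt = BASES[(base_codes[s] + rng.integers(1, 4)) % 4]
        private = s < n_private
        if private:
            grp = private_eligible[rng.integers(len(private_eligible))]
            pool = line_idx_by_group[grp]
            m = int(rng.integers(2, len(pool) + 1))
            carriers = _random_subset(rng, pool, m)
        else:
            grp = ""
            while True:
                m = int(rng.integers(2, max(n_lines - 1, 3)))
                carriers = _random_subset(rng, range(n_lines), m)
                if len({group_of[lines[i]] for i in carriers}) >= 2:
                    break
        genotypes[s, :] = ref
        genotypes[s, carriers] = alt
        rows.append((chrom, pos, ref, alt, grp))
    # shuffle so private loci are not a coordinate-sorted prefix
    order = np.lexsort(([p for _, p, *_ in rows], [c for c, *_ in rows]))
    snp_loci = pd.DataFrame(
        [rows[i] for i in order], columns=["chrom", "pos", "ref", "alt", "private_group"]
    )
    genotypes = genotypes[order]

    inv_ref = [BASES[c] for c in rng.integers(0, 4, size=len(inv_sites))]
    invariant_loci = pd.DataFrame(
        [(c, p, r) for (c, p), r in zip(inv_sites, inv_ref)],
        columns=["chrom", "pos", "ref"],
    )

    # expression truth: absent everywhere / core / variable gene classes
    classes = rng.choice(
        3,
        size=config.n_genes,
        p=[
            config.gene_absent_fraction,
            config.gene_core_fraction,
            1 - config.gene_absent_fraction - config.gene_core_fraction,
        ],
    )
    level_choices = [ExpressionCategory.LOW, ExpressionCategory.MEDIUM, ExpressionCategory.HIGH]
    expr = np.full((config.n_genes, n_lines), ExpressionCategory.NONE, dtype=object)
    for gi in range(config.n_genes):
        if classes[gi] == 0:
            continue
        level = level_choices[rng.choice(3, p=[0.15, 0.75, 0.10])]
        if classes[gi] == 1:
            expr[gi, :] = level
        else:
            k = int(rng.integers(1, n_lines))
            expr[gi, _random_subset(rng, range(n_lines), k)] = level
    expression = pd.DataFrame(
        expr, index=[g.gene_id for g in genes], columns=list(lines)
    )

    # novel transcripts: core / dispensable (some group-private), plus
    # reference-like transcripts the novelty filter must remove
    n_novel = config.n_novel_transcripts
    novel_ids = tuple(f"asm_t{i + 1:04d}" for i in range(n_novel))
    ref_like_ids = tuple(
        f"asm_r{i + 1:04d}" for i in range(config.n_reference_like_transcripts)
    )
    lengths = {
        tid: int(rng.integers(500, 3001)) for tid in (*novel_ids, *ref_like_ids)
    }
    n_core = round(config.core_novel_fraction * n_novel)
    presence = np.zeros((n_novel, n_lines), dtype=bool)
    presence[:n_core, :] = True
    dispensable = list(range(n_core, n_novel))
    n_priv = round(config.group_private_novel_fraction * len(dispensable))
    for k, ti in enumerate(dispensable):
        if k < n_priv:
            grp = private_eligible[rng.integers(len(private_eligible))]
            pool = line_idx_by_group[grp]
            m = int(rng.integers(1, len(pool) + 1))
            presence[ti, _random_subset(rng, pool, m)] = True
        else:
            m = int(rng.integers(1, n_lines))
            presence[ti, _random_subset(rng, range(n_lines), m)] = True
    novel_presence = pd.DataFrame(presence, index=list(novel_ids), columns=list(lines))
    n_multi = round(config.multi_only_novel_fraction * n_novel)
    multi_only = frozenset(
        novel_ids[i] for i in rng.choice(n_novel, size=n_multi, replace=False)
    )

    return Truth(
        lines=lines,
        line_groups=line_groups,
        genes=genes,
        snp_loci=snp_loci,
        genotypes=genotypes,
        invariant_loci=invariant_loci,
        expression=expression,
        novel_ids=novel_ids,
        reference_like_ids=ref_like_ids,
        novel_lengths=lengths,
        novel_presence=novel_presence,
        multi_only=multi_only,
    )


def _counts_from_truth(
    geno: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequencing counts (n_loci, n_lines, 4): depth ~ Poisson(mean_depth);
    each read reports the true base with probability 1 - error_rate, else a
    uniformly chosen other base.  Counts sum to the drawn depth."""
    n_loci, n_lines = geno.shape
    codes = np.vectorize({b: i for i, b in enumerate(BASES)}.get)(geno).astype(np.int8)
    depth = rng.poisson(mean_depth, size=(n_loci, n_lines))
    n_err = rng.binomial(depth, error_rate)
    counts = np.zeros((n_loci, n_lines, 4), dtype=np.int64)
    err_split = rng.multinomial(n_err.ravel(), [1 / 3] * 3).reshape(n_loci, n_lines, 3)
    li, pi = np.meshgrid(np.arange(n_lines), np.arange(n_loci))
    np.add.at(counts, (pi, li, codes), depth - n_err)
    for k in range(3):
        other = (codes + 1 + k) % 4
        np.add.at(counts, (pi, li, other), err_split[:, :, k])
    return counts


def _counts_to_table(
    loci: pd.DataFrame, counts: np.ndarray, lines: Sequence[str]
) -> BaseCountTable:
    depth = counts.sum(axis=2)
    pi, li = np.nonzero(depth > 0)
    df = pd.DataFrame(
        {
            "line_id": np.asarray(lines, dtype=object)[li],
            "chrom": loci["chrom"].to_numpy()[pi],
            "pos": loci["pos"].to_numpy()[pi],
            "count_A": counts[pi, li, 0],
            "count_C": counts[pi, li, 1],
            "count_G": counts[pi, li, 2],
            "count_T": counts[pi, li, 3],
        }
    )
    return BaseCountTable(df)


def simulate_basecounts(truth: Truth, config: SimulationConfig) -> BaseCountTable:
    """RNA-seq base counts at every simulated site (SNP and invariant).

    Zero-depth cells are omitted from the table, so the caller sees those
    (line, position) pairs as having no record and must score them MISSING.
    """
    rng = _stage_rng(config.seed, _STAGE_BASECOUNTS)
    loci, geno = truth.all_loci
    counts = _counts_from_truth(geno, config.mean_depth, config.error_rate, rng)
    return _counts_to_table(loci, counts, truth.lines)


def simulate_gbs_counts(truth: Truth, config: SimulationConfig) -> BaseCountTable:
    """GBS base counts at a random subset of the true SNP loci."""
    rng = _stage_rng(config.seed, _STAGE_GBS)
    n_sites = round(config.gbs_site_fraction * len(truth.snp_loci))
    idx = np.sort(rng.choice(len(truth.snp_loci), size=n_sites, replace=False))
    loci = truth.snp_loci.iloc[idx][["chrom", "pos"]].reset_index(drop=True)
    geno = truth.genotypes[idx]
    counts = _counts_from_truth(geno, config.gbs_mean_depth, config.error_rate, rng)
    return _counts_to_table(loci, counts, truth.lines)


#: (low, high) FPKM sampling ranges per expressed category.
_FPKM_RANGES = {
    ExpressionCategory.LOW: (0.05, 5.0),
    ExpressionCategory.MEDIUM: (5.0, 200.0),
    ExpressionCategory.HIGH: (200.0, 2000.0),
}


def simulate_fpkm_table(truth: Truth, config: SimulationConfig) -> pd.DataFrame:
    """FPKM estimates with 95% CI bounds for every gene x line cell.

    Absent cells get (0, 0, 0).  Expressed cells draw FPKM uniformly from
    their category's range with a CI strictly bracketing it, except that a
    ``fpkm_absent_rate`` fraction of LOW cells is given a zero lower bound,
    emulating sampling dropout of lowly expressed genes.
    """
    rng = _stage_rng(config.seed, _STAGE_FPKM)
    rows = []
    for gene_id, row in truth.expression.iterrows():
        for line_id, cat in row.items():
            if cat is ExpressionCategory.NONE:
                rows.append((gene_id, line_id, 0.0, 0.0, 0.0))
                continue
            lo, hi = _FPKM_RANGES[cat]
            fpkm = float(rng.uniform(lo, hi))
            if fpkm == 0.0:  # open interval (0, 5) for LOW
                fpkm = lo
            conf_lo = fpkm * float(rng.uniform(0.2, 0.8))
            conf_hi = fpkm * (1 + float(rng.uniform(0.2, 0.8)))
            if cat is ExpressionCategory.LOW and rng.random() < config.fpkm_absent_rate:
                conf_lo = 0.0
            rows.append((gene_id, line_id, fpkm, conf_lo, conf_hi))
    return pd.DataFrame(
        rows, columns=["gene_id", "line_id", "fpkm", "conf_lo", "conf_hi"]
    )


def simulate_alignment_summaries(truth: Truth, config: SimulationConfig) -> list:
    """Best-alignment summaries for all representative transcripts.

    Truly novel transcripts are either unaligned (with probability
    ``unaligned_novel_fraction``) or aligned with (coverage, identity)
    drawn so that at least one of the two stays at or below 0.85;
    reference-like transcripts draw both above 0.85 and are therefore
    removed by the default novelty filter.
    """
    from ._model import AlignmentSummary

    rng = _stage_rng(config.seed, _STAGE_ALIGNMENT)
    out = []
    for tid in truth.novel_ids:
        if rng.random() < config.unaligned_novel_fraction:
            out.append(AlignmentSummary(tid, False))
        else:
            while True:
                cov = float(rng.uniform(0.4, 1.0))
                ident = float(rng.uniform(0.4, 1.0))
                if not (cov > 0.85 and ident > 0.85):
                    break
            out.append(AlignmentSummary(tid, True, cov, ident))
    for tid in truth.reference_like_ids:
        cov = float(rng.uniform(0.851, 1.0))
        ident = float(rng.uniform(0.851, 1.0))
        out.append(AlignmentSummary(tid, True, cov, ident))
    return out


def simulate_read_support(truth: Truth, config: SimulationConfig) -> pd.DataFrame:
    """Unique/multi-mapped read counts per novel transcript x line.

    Present transcripts receive at least one uniquely mapping read unless
    flagged multi-only (the paralog-like class), in which case support is
    carried entirely by multi-mapped reads.  Absent cells are zero.
    """
    rng = _stage_rng(config.seed, _STAGE_SUPPORT)
    rows = []
    for tid in truth.novel_ids:
        multi_only = tid in truth.multi_only
        for line_id in truth.lines:
            if truth.novel_presence.loc[tid, line_id]:
                n = 1 + int(rng.poisson(config.support_mean_reads))
                extra = int(rng.poisson(2.0))
                if multi_only:
                    rows.append((tid, line_id, 0, n))
                else:
                    rows.append((tid, line_id, n, extra))
            else:
                rows.append((tid, line_id, 0, 0))
    return pd.DataFrame(
        rows, columns=["transcript_id", "line_id", "unique_reads", "multi_reads"]
    )


def simulate_study(config: SimulationConfig) -> dict:
    """Run every stage once; returns a dict of truth plus all input tables."""
    truth = simulate_population(config)
    return {
        "truth": truth,
        "basecounts": simulate_basecounts(truth, config),
        "gbs_counts": simulate_gbs_counts(truth, config),
        "fpkm": simulate_fpkm_table(truth, config),
        "alignments": simulate_alignment_summaries(truth, config),
        "read_support": simulate_read_support(truth, config),
    }


def evaluate_snp_recovery(
    truth: Truth,
    table: BaseCountTable,
    matrix,
    *,
    min_reads: int = 2,
    min_frac: float = 0.05,
) -> dict:
    """Score a called genotype matrix against the simulated truth.

    A true locus counts as *discoverable* when each of its two alleles has
    at least two carrier lines whose reads would pass the per-line
    thresholds on their true allele — the coverage condition under which
    the caller can possibly confirm both alleles.  Sensitivity is measured
    over discoverable loci; the false-discovery proportion over all
    emitted loci.
    """
    loci, counts = table.pivot(truth.lines)
    key = {(c, p): i for i, (c, p) in enumerate(zip(loci["chrom"], loci["pos"]))}
    total = counts.sum(axis=2)

    truth_pos = set(zip(truth.snp_loci["chrom"], truth.snp_loci["pos"]))
    detected = set(zip(matrix.loci["chrom"], matrix.loci["pos"]))

    n_discoverable = 0
    n_recovered = 0
    for s in range(len(truth.snp_loci)):
        chrom = truth.snp_loci["chrom"].iloc[s]
        pos = truth.snp_loci["pos"].iloc[s]
        ti = key.get((chrom, pos))
        if ti is None:
            continue
        ok_per_allele = []
        for allele in (truth.snp_loci["ref"].iloc[s], truth.snp_loci["alt"].iloc[s]):
            ai = BASES.index(allele)
            carriers = truth.genotypes[s] == allele
            c = counts[ti, carriers, ai]
            t = total[ti, carriers]
            ok_per_allele.append(int(((c >= min_reads) & (c > min_frac * t)).sum()))
        if min(ok_per_allele) >= 2:
            n_discoverable += 1
            if (chrom, pos) in detected:
                n_recovered += 1

    n_false = len(detected - truth_pos)
    return {
        "n_discoverable": n_discoverable,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_discoverable if n_discoverable else float("nan"),
        "n_detected": len(detected),
        "n_false": n_false,
        "fdr": n_false / len(detected) if detected else 0.0,
    }
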