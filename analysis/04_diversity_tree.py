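#!/usr/bin/env python
"""Cluster the panel by genetic distance and test pedigree-group recovery.

Computes pairwise Rogers distances from the called genotype matrix
(pairwise deletion of missing data), builds the neighbor-joining tree,
and checks whether each multi-line pedigree group forms a connected
subtree — the qualitative signature of distinct heterotic pools.
"""
from pathlib import Path

from pantx import diversity, formats_io as io

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    matrix = io.read_vcf(OUT / "snps.vcf")
    dm = diversity.distance_matrix(matrix, min_shared=100)
    dm.to_frame().to_csv(OUT / "rogers_distances.tsv", sep="\t")
    print(f"distances over {len(dm.labels)} lines; "
          f"range {dm.values[dm.values > 0].min():.3f}-{dm.values.max():.3f}")

    tree = diversity.neighbor_joining(dm)
    io.write_newick(tree, OUT / "nj_tree.nwk")

    groups = io.read_line_groups(STUDY / "line_groups.tsv")
    by_group: dict[str, list[str]] = {}
    for g in groups:
        by_group.setdefault(g.group, []).append(g.line_id)
    for group, members in sorted(by_group.items()):
        if len(members) < 2:
            continue
        ok = diversity.group_forms_subtree(tree, members)
        print(f"group {group} ({len(members)} lines): "
              f"{'forms' if ok else 'does NOT form'} a connected subtree")


if __name__ == "__main__":
    main()
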