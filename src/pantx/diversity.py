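"""Rogers genetic distances and neighbor-joining trees for inbred panels.

Rogers' distance averages, over loci, the per-locus Euclidean distance
between allele-frequency vectors, d_l = sqrt(0.5 * sum_a (p_a - q_a)^2).
For fully homozygous lines each frequency is a 0/1 indicator, so d_l is 1
when the alleles differ and 0 otherwise, and the distance reduces to the
proportion of mismatching loci among those compared.  Loci missing in
either line are excluded pairwise.

Neighbor joining follows Saitou & Nei: repeatedly join the pair minimising
Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), with the standard
two-point branch-length formulas.  On an exactly additive matrix the source
tree (topology and lengths) is recovered.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

from ._model import MISSING, GenotypeMatrix, PantxError

__all__ = [
    "UndefinedDistanceError",
    "DistanceMatrix",
    "rogers_distance",
    "distance_matrix",
    "neighbor_joining",
    "group_forms_subtree",
]


class UndefinedDistanceError(PantxError):
    """Too few pairwise-complete loci to define a distance."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair shared-locus counts."""

    labels: tuple[str, ...]
    values: np.ndarray
    n_shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("negative distance")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _encode(vec: Sequence[str]) -> np.ndarray:
    return np.asarray(vec, dtype=object)


def rogers_distance(
    g1: Sequence[str],
    g2: Sequence[str],
    *,
    min_shared: int = 1,
) -> float:
    """Rogers distance between two homozygous genotype vectors.

    Vectors are aligned on the same loci; entries are nucleotides or
    MISSING.  Loci missing in either vector are dropped (pairwise
    deletion); if fewer than ``min_shared`` loci remain the distance is
    undefined and :class:`UndefinedDistanceError` is raised.
    """
    a, b = _encode(g1), _encode(g2)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n < min_shared:
        raise UndefinedDistanceError(f"only {n} shared loci (< {min_shared})")
    return float((a[shared] != b[shared]).mean())


def distance_matrix(
    matrix: GenotypeMatrix,
    *,
    min_shared: int = 100,
) -> DistanceMatrix:
    """All pairwise Rogers distances for the lines of a genotype matrix.

    ``min_shared`` (default 100 loci) guards against distances estimated
    from too few pairwise-complete loci; any offending pair aborts the
    computation with a report of all such pairs.
    """
    lines = matrix.lines
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    calls = matrix.calls.to_numpy(dtype=object)
    present = calls != MISSING
    n = len(lines)
    values = np.zeros((n, n))
    shared_counts = np.zeros((n, n), dtype=np.int64)
    bad_pairs = []
    for i in range(n):
        shared_counts[i, i] = int(present[:, i].sum())
        for j in range(i + 1, n):
            shared = present[:, i] & present[:, j]
            ns = int(shared.sum())
            shared_counts[i, j] = shared_counts[j, i] = ns
            if ns < min_shared:
                bad_pairs.append((lines[i], lines[j], ns))
                continue
            d = float((calls[shared, i] != calls[shared, j]).mean())
            values[i, j] = values[j, i] = d
    if bad_pairs:
        report = "; ".join(f"{a}-{b}: {k} loci" for a, b, k in bad_pairs)
        raise UndefinedDistanceError(f"pairs below min_shared={min_shared}: {report}")
    return DistanceMatrix(tuple(lines), values, shared_counts)


def _clamped_limbs(d_ij: float, li: float) -> tuple[float, float]:
    """Clamp a negative limb to 0, moving the deficit to its sister so the
    two-limb sum d(i,j) is preserved (Kuhner-Felsenstein convention)."""
    lj = d_ij - li
    if li < 0:
        return 0.0, d_ij
    if lj < 0:
        return d_ij, 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> skbio.TreeNode:
    """Build an unrooted NJ tree; returns a tree rooted at a trifurcation.

    Q-matrix ties break on the lowest (row, column) index pair in the
    current working order, so the output is deterministic.  Negative branch
    lengths are clamped to zero with the deficit transferred to the sister
    branch.  Requires at least three taxa.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [skbio.TreeNode(name=l) for l in dm.labels]
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        li, lj = _clamped_limbs(D[i, j], li)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = skbio.TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = np.maximum(d_new[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return skbio.TreeNode(children=[a, b, c])


def group_forms_subtree(tree: skbio.TreeNode, group_leaves: Iterable[str]) -> bool:
    """True when the group's leaves form a connected subtree of the unrooted
    tree, i.e. some edge bipartitions the leaf set into (group, rest)."""
    tips = {t.name for t in tree.tips()}
    group = set(group_leaves)
    if not group <= tips:
        raise ValueError("group contains labels not in the tree")
    if len(group) <= 1 or group == tips:
        return True
    complement = tips - group
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        subset = {t.name for t in node.tips()}
        if subset == group or subset == complement:
            return True
    return False
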