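"""Pairwise distances, deterministic UPGMA, level partitions, Newick output.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two clusters with the smallest size-weighted average pairwise distance;
the merge is placed at height = that distance / 2, which makes root-to-leaf
path lengths equal (an ultrametric tree).  Ties are broken by the
lexicographically smallest pair of cluster founding labels (the smallest
leaf label inside each cluster), so the tree — and every subgroup partition
cut from it — is bit-reproducible and invariant to the input order of the
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._alphabet import GAP_CODE
from .msa_io import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "UpgmaTree",
    "PartitionSet",
    "pairwise_distance",
    "upgma",
    "tree_levels",
    "write_newick",
    "cophenetic_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if np.isnan(d).any():
            raise ValueError("distance matrix contains NaN")
        if (d < 0).any():
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, sep="\t", index_label="id"
        )


@dataclass(frozen=True)
class UpgmaTree:
    """Binary UPGMA merge tree over ``labels``.

    Leaves are nodes ``0..N-1`` (height 0); internal node ``N+m`` is created
    by merge ``m`` of ``merges``, each a ``(left, right, height)`` triple
    with non-decreasing heights.  ``children[node]`` gives the two children
    of an internal node, ordered by founding label (smallest contained leaf
    label).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    heights: np.ndarray  # per node, leaves first

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        if node < self.n_leaves:
            raise ValueError(f"node {node} is a leaf")
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def leaves_below(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        a, b = self.children(node)
        return self.leaves_below(a) + self.leaves_below(b)


@dataclass(frozen=True)
class PartitionSet:
    """Subgroup assignment of every sequence at every tree level.

    ``levels[k]`` (k = 1..N) maps identifier -> subgroup index in
    ``0..k-1``; level 1 is a single subgroup, level N the singletons, and
    each level refines the one above it.
    """

    labels: tuple[str, ...]
    levels: dict[int, dict[str, int]]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def groups(self, k: int) -> list[list[str]]:
        """Members of each subgroup at level ``k``, index order."""
        out: dict[int, list[str]] = {}
        for ident, g in self.levels[k].items():
            out.setdefault(g, []).append(ident)
        return [out[g] for g in sorted(out)]


def pairwise_distance(aln: Alignment) -> DistanceMatrix:
    """p-distance over pairwise-comparable columns.

    For each pair, the fraction of mismatching columns among those where
    both sequences carry a standard residue (gaps and ambiguity codes are
    excluded per pair).  Pairs with no comparable column get distance 1.0
    and a logged warning.
    """
    codes = aln.codes
    n = aln.n_sequences
    standard = codes < GAP_CODE
    d = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        comp = standard[i] & standard[i + 1 :]
        n_comp = comp.sum(axis=1)
        mism = ((codes[i] != codes[i + 1 :]) & comp).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(n_comp > 0, mism / np.maximum(n_comp, 1), 1.0)
        if (n_comp == 0).any():
            for j in np.nonzero(n_comp == 0)[0]:
                logger.warning(
                    "no comparable columns between %r and %r; distance set to 1.0",
                    aln.ids[i],
                    aln.ids[i + 1 + j],
                )
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(labels=aln.ids, d=d)


def upgma(dm: DistanceMatrix) -> UpgmaTree:
    """Build the deterministic UPGMA tree for a distance matrix.

    Average linkage with size weighting: after merging clusters *a*, *b*
    the distance to any other cluster *c* is
    ``(n_a * d(a,c) + n_b * d(b,c)) / (n_a + n_b)``, which keeps every
    cluster-to-cluster value equal to the arithmetic mean of the raw
    leaf-to-leaf distances across the two clusters.
    """
    n = dm.n
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    # Track the SUM of leaf-pair distances per cluster pair, not the running
    # average: sums merge by exact addition, so the average is always
    # sum / (n_a * n_b) of the raw entries and tie detection cannot drift
    # through repeated rounding of intermediate averages.
    pairsum: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pairsum[(i, j)] = float(dm.d[i, j])
    size = {i: 1 for i in range(n)}
    founder = {i: dm.labels[i] for i in range(n)}  # smallest contained leaf label
    active = list(range(n))
    heights = np.zeros(2 * n - 1)
    merges: list[tuple[int, int, float]] = []

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for m in range(n - 1):
        # pick minimal distance; ties by founding-label pair
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dv = pairsum[key(a, b)] / (size[a] * size[b])
                fa, fb = founder[a], founder[b]
                tie = (min(fa, fb), max(fa, fb))
                if best is None or (dv, tie) < (best[0], best[1]):
                    best = (dv, tie, a, b)
        dv, _, a, b = best  # type: ignore[misc]
        if founder[b] < founder[a]:
            a, b = b, a
        new = n + m
        heights[new] = dv / 2.0
        merges.append((a, b, dv / 2.0))
        size[new] = size[a] + size[b]
        founder[new] = min(founder[a], founder[b])
        active.remove(a)
        active.remove(b)
        for c in active:
            pairsum[key(new, c)] = pairsum[key(a, c)] + pairsum[key(b, c)]
        active.append(new)

    return UpgmaTree(labels=dm.labels, merges=tuple(merges), heights=heights)


def tree_levels(tree: UpgmaTree) -> PartitionSet:
    """Partition of the leaves at every level k = 1..N.

    Level k is obtained by undoing the last k-1 merges (equivalently,
    cutting the dendrogram between consecutive merge heights).  Subgroup
    indices are assigned by the smallest leaf index each subgroup contains,
    so the labelling is deterministic and order-free.
    """
    n = tree.n_leaves
    levels: dict[int, dict[str, int]] = {}
    active: list[int] = [tree.root]
    for k in range(1, n + 1):
        # assign subgroup index by founding leaf for determinism
        members: list[tuple[int, list[int]]] = []
        for node in active:
            leaves = tree.leaves_below(node)
            members.append((min(leaves), leaves))
        members.sort()
        assignment: dict[str, int] = {}
        for g, (_, leaves) in enumerate(members):
            for leaf in leaves:
                assignment[tree.labels[leaf]] = g
        levels[k] = assignment
        if k < n:
            # undo the most recent merge still active
            undo = max(node for node in active if node >= n)
            a, b, _ = tree.merges[undo - n]
            active.remove(undo)
            active.extend([a, b])
    return PartitionSet(labels=tree.labels, levels=levels)


def _escape_newick_label(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UpgmaTree, path=None) -> str:
    """Serialise the tree to Newick with branch lengths.

    Branch length of a child is the parent height minus the child height;
    children are emitted in founding-index order.  Returns the Newick
    string; writes it to ``path`` when given.
    """

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - tree.heights[node]
        if node < tree.n_leaves:
            return f"{_escape_newick_label(tree.labels[node])}:{bl:.10g}"
        a, b = tree.children(node)
        inner = f"({render(a, tree.heights[node])},{render(b, tree.heights[node])})"
        if parent_height is not None and node != tree.root:
            return f"{inner}:{bl:.10g}"
        return inner

    root = tree.root
    a, b = tree.children(root)
    h = tree.heights[root]
    text = f"({render(a, h)},{render(b, h)});"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def cophenetic_matrix(tree: UpgmaTree) -> np.ndarray:
    """Leaf-pair cophenetic distances (2 x height of the lowest common
    ancestor); UPGMA guarantees these are ultrametric."""
    n = tree.n_leaves
    coph = np.zeros((n, n))
    for m, (a, b, h) in enumerate(tree.merges):
        la = tree.leaves_below(a)
        lb = tree.leaves_below(b)
        for i in la:
            for j in lb:
                coph[i, j] = coph[j, i] = 2.0 * h
    return coph
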