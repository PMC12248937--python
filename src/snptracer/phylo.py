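"""Unshared-variant distances and neighbor-joining tree construction.

The distance between two strains is the number of biallelic loci at which
exactly one of the two carries the alternate allele (allele presence, not
genotype class: het and hom-alt both count as "carries").  The tree builder
is a from-scratch Saitou--Nei neighbor-joining implementation with
deterministic tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .genomes_io import GenotypeMatrix, Genotype

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "pairwise_unshared",
    "neighbor_joining",
    "write_distance_tsv",
    "read_distance_tsv",
]


@dataclass
class DistanceMatrix:
    strain_names: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.strain_names)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match strain count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("non-zero diagonal")

    @property
    def n(self) -> int:
        return len(self.strain_names)


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode", length: float) -> None:
        self.children.append((child, length))


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at an internal node of degree >= 2."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        labels: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                labels.append(node.label or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return labels

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.label or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.6g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set splits induced by internal edges (smaller side, by content).

        The split for each edge is reported as the frozenset of leaves on the
        child side; trivial splits (single leaf / all leaves) are excluded.
        Two unrooted trees over the same leaves are isomorphic iff their
        bipartition sets (canonicalized) are equal.
        """
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.label or ""])
            below: set[str] = set()
            for child, _ in node.children:
                sub = walk(child)
                if 1 < len(sub) < len(all_leaves) - 1:
                    canon = min(sub, all_leaves - sub, key=lambda s: sorted(s))
                    splits.add(canon)
                below |= sub
            return frozenset(below)

        walk(self.root)
        return splits


def pairwise_unshared(
    matrix: GenotypeMatrix, strict_genotype: bool = False
) -> DistanceMatrix:
    """Count, per strain pair, the loci at which their alleles disagree.

    Default mode counts allele presence (het vs hom-alt at the same locus is
    *shared*); ``strict_genotype`` instead counts loci with unequal genotype
    classes.  Loci where either strain is missing are skipped for that pair.
    """
    names = matrix.strain_names
    n = len(names)
    if not matrix.records:
        warnings.warn("empty record list: all pairwise distances are zero")
        return DistanceMatrix(strain_names=list(names), d=np.zeros((n, n)))

    g = matrix.genotype_array()
    missing = g == int(Genotype.MISSING)
    d = np.zeros((n, n))
    if strict_genotype:
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~missing[i] & ~missing[j]
                d[i, j] = d[j, i] = np.sum(ok & (g[i] != g[j]))
    else:
        carries = (g == int(Genotype.HET)) | (g == int(Genotype.HOM_ALT))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~missing[i] & ~missing[j]
                d[i, j] = d[j, i] = np.sum(ok & (carries[i] ^ carries[j]))
    return DistanceMatrix(strain_names=list(names), d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic Saitou--Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i, j) = (n-2) d(i, j) - r_i - r_j,
    with ties broken by the smallest (i, j) index pair in the current node
    ordering.  Negative branch lengths are clamped to zero.
    """
    n = dm.n
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    if n == 2:
        half = float(dm.d[0, 1]) / 2.0
        root = TreeNode()
        root.add(TreeNode(label=dm.strain_names[0]), half)
        root.add(TreeNode(label=dm.strain_names[1]), half)
        return PhyloTree(root=root)

    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=name) for name in dm.strain_names]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        assert best is not None
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        parent.add(nodes[i], li)
        parent.add(nodes[j], lj)

        new_d = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            dist = 0.5 * (d[i, ka] + d[j, ka] - d[i, j])
            new_d[a, m - 2] = new_d[m - 2, a] = max(dist, 0.0)
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    # final three nodes join at one internal vertex (degree 3, unrooted)
    r = d.sum(axis=1)
    root = TreeNode()
    for i in range(3):
        length = 0.5 * (r[i] - d[(i + 1) % 3, (i + 2) % 3])
        root.add(nodes[i], max(length, 0.0))
    return PhyloTree(root=root)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(dm.strain_names) + "\n")
        for i, name in enumerate(dm.strain_names):
            row = "\t".join(f"{dm.d[i, j]:g}" for j in range(dm.n))
            fh.write(f"{name}\t{row}\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read a square TSV matrix; a PHYLIP-style lower triangle also works."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    header = lines[0].split("\t")
    if header[0] == "strain":
        names = header[1:]
        rows = [ln.split("\t") for ln in lines[1:]]
        d = np.array([[float(x) for x in row[1:]] for row in rows])
        return DistanceMatrix(strain_names=names, d=d)
    # PHYLIP: first line is the taxon count, rows are name + lower triangle
    n = int(lines[0].split()[0])
    names, d = [], np.zeros((n, n))
    for i, ln in enumerate(lines[1 : n + 1]):
        parts = ln.split()
        names.append(parts[0])
        for j, x in enumerate(parts[1 : i + 1]):
            d[i, j] = d[j, i] = float(x)
    return DistanceMatrix(strain_names=names, d=d)
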