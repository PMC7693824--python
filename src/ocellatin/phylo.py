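"""Similarity cladogram over peptide sets.

Distances are 1 - identity fraction from the family alignment conventions;
trees are built by UPGMA (default, the cladogram) or neighbor-joining and
exported as Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .compare import global_align
from .datasets import PeptideRecord


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal not zero")
        if (self.d < 0).any():
            raise ValueError("negative distance")


def distance_matrix(records: Sequence[PeptideRecord]) -> DistanceMatrix:
    """Pairwise 1 - identity_fraction distances over a record set."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    labels = [r.name for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i].sequence, records[j].sequence)
            d[i, j] = d[j, i] = 1.0 - res.n_identical / res.length
    return DistanceMatrix(labels=tuple(labels), d=d)


def _to_bio_dm(dm: DistanceMatrix) -> _BioDM:
    # Sort labels so agglomeration ties resolve by name order, not input order.
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    names = [dm.labels[i] for i in order]
    matrix = [
        [float(dm.d[order[i], order[j]]) for j in range(i + 1)]
        for i in range(len(order))
    ]
    return _BioDM(names=names, matrix=matrix)


def build_tree(dm: DistanceMatrix, method: str = "upgma") -> Tree:
    """Agglomerate a distance matrix into a tree (UPGMA or NJ)."""
    constructor = DistanceTreeConstructor()
    bio_dm = _to_bio_dm(dm)
    if method == "upgma":
        tree = constructor.upgma(bio_dm)
    elif method == "nj":
        tree = constructor.nj(bio_dm)
    else:
        raise ValueError(f"unknown method {method!r}")
    for clade in tree.get_nonterminals():
        clade.name = None  # drop Inner# labels; cladogram nodes are anonymous
    return tree


def leaf_names(tree: Tree) -> set[str]:
    return {leaf.name for leaf in tree.get_terminals()}


def is_monophyletic(tree: Tree, leaves: Sequence[str]) -> bool:
    """True iff the smallest subtree containing ``leaves`` has no others."""
    wanted = set(leaves)
    present = leaf_names(tree)
    missing = wanted - present
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    if len(wanted) <= 1 or wanted == present:
        return True
    mrca = tree.common_ancestor(
        [leaf for leaf in tree.get_terminals() if leaf.name in wanted]
    )
    return {leaf.name for leaf in mrca.get_terminals()} == wanted


def to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> Tree:
    return Phylo.read(io.StringIO(text), "newick")


def leaf_depths(tree: Tree) -> dict[str, float]:
    """Root-to-leaf branch-length distances (UPGMA trees are ultrametric)."""
    return {
        clade.name: depth
        for clade, depth in tree.depths().items()
        if clade.is_terminal()
    }


def tree_distance(tree: Tree, a: str, b: str) -> float:
    """Leaf-to-leaf path length along the tree."""
    return float(tree.distance(a, b))


def family_cladogram(
    records: Sequence[PeptideRecord], method: str = "upgma"
) -> Tree:
    return build_tree(distance_matrix(records), method=method)
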