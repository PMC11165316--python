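"""Neighbor-joining trees from gap-distance matrices.

Standard Saitou–Nei agglomeration: at each step join the pair (i, j)
minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with limb lengths from the usual NJ formulas.  Gap matrices are full of
exact ties (zero blocks are common), so ties in Q are broken
deterministically by the lexicographically smallest label pair, where a
cluster is labelled by its smallest member leaf.  Negative limb-length
estimates are clamped to zero after estimation (downstream clade costs
must be non-negative); the clamps are recorded on the returned tree.

The tree is conceptually unrooted; the final agglomeration node serves
as root for traversal, which is all the clade search needs (leaf
partitions).  Trees are Bio.Phylo objects, so newick serialization and
standard traversal come for free.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .gapdist import GapDistanceMatrix


def _check_matrix(matrix: GapDistanceMatrix) -> None:
    d = np.asarray(matrix.d, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")


def nj_tree(matrix: GapDistanceMatrix) -> Tree:
    """Build a neighbor-joining tree from a gap-distance matrix.

    One label yields a single-leaf tree; two labels a single edge split
    evenly; three or more the standard NJ agglomeration ending in a
    trifurcating root (the unrooted NJ tree rooted at the last join).
    The returned tree carries a ``clamped_branches`` list naming leaves
    or clusters whose estimated limb length was negative and set to 0.
    """
    _check_matrix(matrix)
    labels = list(matrix.labels)
    clamped: list[str] = []

    def _limb(length: float, key: str) -> float:
        if length < 0:
            clamped.append(key)
            return 0.0
        return length

    if len(labels) == 0:
        raise ValueError("empty distance matrix")
    if len(labels) == 1:
        tree = Tree(root=Clade(name=labels[0]))
        tree.clamped_branches = clamped
        return tree
    if len(labels) == 2:
        d = matrix.distance(labels[0], labels[1])
        root = Clade()
        root.clades = [
            Clade(name=labels[0], branch_length=_limb(d / 2, labels[0])),
            Clade(name=labels[1], branch_length=_limb(d / 2, labels[1])),
        ]
        tree = Tree(root=root)
        tree.clamped_branches = clamped
        return tree

    # active clusters keyed by their smallest leaf label (keys are unique
    # because leaf sets are disjoint); dist holds inter-cluster distances.
    clades: dict[str, Clade] = {lab: Clade(name=lab) for lab in labels}
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist[(min(a, b), max(a, b))] = matrix.distance(a, b)

    def d_of(a: str, b: str) -> float:
        return dist[(min(a, b), max(a, b))]

    while len(clades) > 3:
        keys = sorted(clades)
        n = len(keys)
        r = {k: sum(d_of(k, other) for other in keys if other != k) for k in keys}
        best_q = math.inf
        best_pair: tuple[str, str] | None = None
        for ii, a in enumerate(keys):
            for b in keys[ii + 1 :]:
                q = (n - 2) * d_of(a, b) - r[a] - r[b]
                if q < best_q:
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        dab = d_of(a, b)
        limb_a = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        limb_b = dab - limb_a
        child_a, child_b = clades.pop(a), clades.pop(b)
        child_a.branch_length = _limb(limb_a, a)
        child_b.branch_length = _limb(limb_b, b)
        new = Clade()
        new.clades = [child_a, child_b]
        new_key = min(a, b)
        for k in list(clades):
            duk = 0.5 * (d_of(a, k) + d_of(b, k) - dab)
            dist[(min(new_key, k), max(new_key, k))] = duk
        clades[new_key] = new

    # final trifurcation: three-point formulas on the remaining clusters
    ka, kb, kc = sorted(clades)
    dab, dac, dbc = d_of(ka, kb), d_of(ka, kc), d_of(kb, kc)
    limbs = {
        ka: (dab + dac - dbc) / 2,
        kb: (dab + dbc - dac) / 2,
        kc: (dac + dbc - dab) / 2,
    }
    root = Clade()
    for k in (ka, kb, kc):
        child = clades[k]
        child.branch_length = _limb(limbs[k], k)
        root.clades.append(child)
    tree = Tree(root=root)
    tree.clamped_branches = clamped
    return tree


def clades_of(tree: Tree) -> Iterator[tuple[Clade, frozenset[str]]]:
    """Yield every internal node with its descendant leaf set, preorder.

    A single-leaf tree yields nothing (a leaf is not a clade here).
    Deterministic: traversal order follows the stored child order, which
    nj_tree fixes by the lexicographic cluster keys.
    """
    leaf_sets: dict[int, frozenset[str]] = {}

    def fill(clade: Clade) -> frozenset[str]:
        if clade.is_terminal():
            s = frozenset([clade.name])
        else:
            s = frozenset().union(*(fill(c) for c in clade.clades))
        leaf_sets[id(clade)] = s
        return s

    fill(tree.root)
    for clade in tree.find_clades(order="preorder"):
        if not clade.is_terminal():
            yield clade, leaf_sets[id(clade)]


def leaf_path_length(tree: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    return tree.distance(a, b)
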