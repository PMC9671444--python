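"""Rooted-tree balance indices and their normalization.

Computes the Sackin, Colless, total cophenetic, and rooted quartet indices of
leaf-labeled rooted trees, builds the two extreme topologies — the caterpillar
``K_n`` (every internal node has a leaf child; most unbalanced) and the
maximally balanced tree ``B_n`` (every internal node splits its leaves as
evenly as possible) — and rescales any index to [0, 1] per leaf count using
its extreme values.  The ``B_n`` side of each extreme comes from the closed
formulas of :mod:`halfrec.sequences` (which this layer reproduces by direct
computation on the constructed trees); the ``K_n`` side is computed directly
on the caterpillar.

Branch lengths and internal labels in Newick input are parsed and ignored:
every index here depends on topology only.  Trees are treated as unordered
for index purposes; child order is preserved only for round-trip output.
Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import dendropy

from .sequences import colless_min, cophenetic_min, quartet_max, sackin_min

__all__ = [
    "TreeNode",
    "RootedTree",
    "NewickError",
    "BifurcationError",
    "parse_newick",
    "write_newick",
    "caterpillar",
    "max_balanced",
    "random_bifurcating",
    "sackin",
    "colless",
    "cophenetic",
    "cophenetic_pairwise",
    "quartet_index",
    "quartet_index_bruteforce",
    "extreme_values",
    "normalize",
    "index_bundle",
]

INDEX_NAMES = ("sackin", "colless", "cophenetic", "quartet")


class NewickError(ValueError):
    """Malformed Newick input or invalid leaf labeling."""


class BifurcationError(ValueError):
    """An index defined only for bifurcating trees was asked of a
    multifurcating one."""


@dataclass
class TreeNode:
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RootedTree:
    """A rooted tree with uniquely labeled leaves.

    Internal nodes have at least two children; the root may itself be a leaf
    only in the degenerate single-leaf tree.
    """

    root: TreeNode

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        labels = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                if not node.label:
                    raise NewickError("every leaf must carry a label")
                labels.append(node.label)
            else:
                if len(node.children) < 2 and node is not self.root:
                    raise NewickError("internal nodes must have >= 2 children")
                if len(node.children) == 1:
                    raise NewickError("unifurcations are not supported")
                stack.extend(node.children)
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def leaves(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(reversed(node.children))

    def is_bifurcating(self) -> bool:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                if len(node.children) != 2:
                    return False
                stack.extend(node.children)
        return True

    def postorder(self):
        """Yield (node, children-results ready) bottom-up."""
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick tree; branch lengths and internal labels
    are accepted and discarded."""
    if not text.strip().endswith(";"):
        raise NewickError("Newick input must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        kids = dnode.child_nodes()
        if not kids:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            return TreeNode(label=label)
        return TreeNode(label=None, children=[convert(c) for c in kids])

    return RootedTree(root=convert(dtree.seed_node))


def write_newick(tree: RootedTree) -> str:
    """Topology-and-labels Newick serialization (no branch lengths)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(tree.root) + ";"


def _labels(n: int) -> list[str]:
    return [f"L{i}" for i in range(1, n + 1)]


def caterpillar(n: int) -> RootedTree:
    """The rooted caterpillar ``K_n``: each internal node has a leaf child.

    Leaf ``L1`` hangs off the root; ``L(n-1)`` and ``Ln`` form the deepest
    cherry, so the depth profile is ``1, 2, ..., n-2, n-1, n-1``.
    """
    if n < 2:
        raise ValueError("caterpillar needs n >= 2")
    labels = _labels(n)
    node = TreeNode(children=[TreeNode(label=labels[-2]), TreeNode(label=labels[-1])])
    for lab in reversed(labels[:-2]):
        node = TreeNode(children=[TreeNode(label=lab), node])
    return RootedTree(root=node)


def max_balanced(n: int) -> RootedTree:
    """The maximally balanced tree ``B_n``: the root splits its leaves as
    ``ceil(n/2)`` / ``floor(n/2)``, recursively."""
    if n < 1:
        raise ValueError("max_balanced needs n >= 1")
    labels = iter(_labels(n))

    def build(k: int) -> TreeNode:
        if k == 1:
            return TreeNode(label=next(labels))
        return TreeNode(children=[build((k + 1) // 2), build(k // 2)])

    tree = RootedTree(root=build(n))
    for node in tree.postorder():
        if not node.is_leaf:
            counts = [_leaf_count(c) for c in node.children]
            assert abs(counts[0] - counts[1]) <= 1
    return tree


def _leaf_count(node: TreeNode) -> int:
    return 1 if node.is_leaf else sum(_leaf_count(c) for c in node.children)


def random_bifurcating(n: int, rng) -> RootedTree:
    """Uniform-ish random bifurcating topology on n labeled leaves, built by
    repeatedly joining two random subtrees (deterministic given the rng)."""
    if n < 2:
        raise ValueError("random_bifurcating needs n >= 2")
    forest = [TreeNode(label=lab) for lab in _labels(n)]
    while len(forest) > 1:
        i, j = rng.sample(range(len(forest)), 2)
        a, b = forest[i], forest[j]
        forest = [x for k, x in enumerate(forest) if k not in (i, j)]
        forest.append(TreeNode(children=[a, b]))
    return RootedTree(root=forest[0])


def _annotate(tree: RootedTree):
    """Per-node leaf counts and depths."""
    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[id(node)] = 1 if node.is_leaf else sum(
            counts[id(c)] for c in node.children
        )
    depths: dict[int, int] = {id(tree.root): 0}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            depths[id(c)] = depths[id(node)] + 1
            stack.append(c)
    return counts, depths


def sackin(tree: RootedTree) -> Fraction:
    """Sum of the leaf depths."""
    _, depths = _annotate(tree)
    return Fraction(sum(depths[id(leaf)] for leaf in tree.leaves()))


def colless(tree: RootedTree) -> Fraction:
    """Sum over internal nodes of ``|kappa_left - kappa_right|``; bifurcating
    trees only."""
    if not tree.is_bifurcating():
        raise BifurcationError("the Colless index requires a bifurcating tree")
    counts, _ = _annotate(tree)
    acc = 0
    for node in tree.postorder():
        if not node.is_leaf:
            left, right = node.children
            acc += abs(counts[id(left)] - counts[id(right)])
    return Fraction(acc)


def cophenetic(tree: RootedTree) -> Fraction:
    """Total cophenetic index: sum over leaf pairs of their LCA's depth,
    computed as ``sum_{v != root} C(kappa_v, 2)``."""
    counts, _ = _annotate(tree)
    acc = 0
    for node in tree.postorder():
        if node is not tree.root:
            acc += comb(counts[id(node)], 2)
    return Fraction(acc)


def cophenetic_pairwise(tree: RootedTree) -> Fraction:
    """Reference evaluator: explicit loop over leaf pairs and their LCA."""
    parent = {id(tree.root): None}
    nodes = {id(tree.root): tree.root}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            parent[id(c)] = node
            nodes[id(c)] = c
            stack.append(c)
    _, depths = _annotate(tree)

    def ancestors(node):
        path = []
        while node is not None:
            path.append(id(node))
            node = parent[id(node)]
        return path

    leaves = list(tree.leaves())
    acc = 0
    for u, v in itertools.combinations(leaves, 2):
        anc_u = ancestors(u)
        anc_v = set(ancestors(v))
        lca = next(x for x in anc_u if x in anc_v)
        acc += depths[lca]
    return Fraction(acc)


def quartet_index(tree: RootedTree) -> Fraction:
    """Rooted quartet index: the number of 4-leaf induced subtrees that are
    fully symmetric (two cherries), counted as
    ``sum over internal v of C(kappa_v1, 2) C(kappa_v2, 2)`` — each symmetric
    quartet is rooted at exactly one node with a 2-2 leaf split."""
    if not tree.is_bifurcating():
        raise BifurcationError("the quartet index requires a bifurcating tree")
    counts, _ = _annotate(tree)
    acc = 0
    for node in tree.postorder():
        if not node.is_leaf:
            left, right = node.children
            acc += comb(counts[id(left)], 2) * comb(counts[id(right)], 2)
    return Fraction(acc)


def quartet_index_bruteforce(tree: RootedTree) -> Fraction:
    """Reference evaluator enumerating all C(n, 4) leaf quadruples and testing
    whether the induced topology is two cherries (intended for n <= ~40)."""
    if not tree.is_bifurcating():
        raise BifurcationError("the quartet index requires a bifurcating tree")
    # record, for each node, the set of leaf labels below it
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset({node.label})
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )
    internal = [n for n in tree.postorder() if not n.is_leaf]
    leaves = [leaf.label for leaf in tree.leaves()]
    acc = 0
    for quad in itertools.combinations(leaves, 4):
        qset = set(quad)
        # the induced root is the smallest node containing all four
        lca = min(
            (n for n in internal if qset <= below[id(n)]),
            key=lambda n: len(below[id(n)]),
        )
        left, right = lca.children
        if len(qset & below[id(left)]) == 2:
            acc += 1
    return Fraction(acc)


_INDEX_FUNCS = {
    "sackin": sackin,
    "colless": colless,
    "cophenetic": cophenetic,
    "quartet": quartet_index,
}

_MIN_CLOSED = {
    "sackin": sackin_min,
    "colless": colless_min,
    "cophenetic": cophenetic_min,
}


def extreme_values(index: str, n: int) -> tuple[Fraction, Fraction]:
    """(min, max) of an index over bifurcating trees with n leaves.

    The balanced-side extreme comes from the closed formulas (minimum for
    Sackin/Colless/cophenetic, maximum for the quartet index); the
    caterpillar-side extreme is computed directly on ``K_n``.
    """
    if index not in _INDEX_FUNCS:
        raise KeyError(f"unknown index {index!r}; known: {sorted(_INDEX_FUNCS)}")
    if n < 2:
        raise ValueError("extremes need n >= 2")
    kat = caterpillar(n)
    if index == "quartet":
        return quartet_index(kat), quartet_max(n)
    return _MIN_CLOSED[index](n), _INDEX_FUNCS[index](kat)


def normalize(index: str, tree: RootedTree) -> Fraction:
    """Affine rescaling of an index to [0, 1] for the tree's leaf count,
    oriented so that 0 means maximally balanced and 1 maximally unbalanced
    (the quartet index, which is largest on balanced trees, is inverted)."""
    n = tree.n_leaves
    lo, hi = extreme_values(index, n)
    if lo == hi:
        raise ValueError(
            f"the {index} index has a degenerate range at n = {n}; "
            "normalization is undefined"
        )
    value = _INDEX_FUNCS[index](tree)
    if index == "quartet":
        return (hi - value) / (hi - lo)
    return (value - lo) / (hi - lo)


def index_bundle(tree: RootedTree, normalized: bool = False) -> dict:
    """All four indices of a tree (Colless/quartet only when bifurcating)."""
    bifurcating = tree.is_bifurcating()
    out = {"n": tree.n_leaves}
    for name in INDEX_NAMES:
        if name in ("colless", "quartet") and not bifurcating:
            out[name] = None
            continue
        out[name] = _INDEX_FUNCS[name](tree)
        if normalized:
            try:
                out[f"{name}_norm"] = normalize(name, tree)
            except ValueError:
                out[f"{name}_norm"] = None
    return out
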