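"""Phylogeny handling for the codon-likelihood engine.

Trees are read with dendropy and flattened into postorder arrays. Branch
lengths are in expected substitutions per codon. Branch-model analyses mark
foreground branches with the ``#1`` suffix convention (on a leaf name or
after a closing parenthesis), which survives Newick round trips.

The 4-taxon genome screen uses a completely unresolved star topology: every
leaf attaches to a single internal node, so each taxon has its own branch
and "branch of interest" is synonymous with "taxon of interest".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

_TAG_RE = re.compile(r"(?:\s*#\s*(\d+)|__TAG(\d+)__)\s*$")
# '#1' is not legal newick for most parsers; rewrite to a label-safe marker,
# accepting the tag before or after the branch length
_HASH_AFTER_LENGTH_RE = re.compile(r":\s*([0-9.eE+\-]+)\s*#\s*(\d+)")
_HASH_RE = re.compile(r"\s*#\s*(\d+)")


@dataclass
class Branch:
    """One edge of the (unrooted) tree, identified by its child node."""

    name: str           # leaf name, or internal node id like "node7"
    parent: int         # index into the node list; -1 for the root
    length: float
    tag: int = 0        # 0 = background, 1.. = foreground label
    leaf_taxon: str | None = None  # set iff the child node is a leaf


@dataclass
class Tree:
    """Rooted representation (root = arbitrary internal node) in postorder.

    ``nodes[i]`` is the branch subtending node i; nodes are listed so that
    children always precede parents, with the root last (its branch length
    is ignored).
    """

    nodes: list[Branch]
    taxa: list[str] = field(init=False)

    def __post_init__(self):
        self.taxa = [b.leaf_taxon for b in self.nodes if b.leaf_taxon is not None]

    # ------------------------------------------------------------ access

    @property
    def n_branches(self) -> int:
        return len(self.nodes) - 1  # root has no branch

    def branch_names(self) -> list[str]:
        return [b.name for b in self.nodes[:-1]]

    def branch_lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.nodes[:-1]], dtype=float)

    def with_branch_lengths(self, lengths: np.ndarray) -> "Tree":
        nodes = [Branch(b.name, b.parent, b.length, b.tag, b.leaf_taxon) for b in self.nodes]
        for b, t in zip(nodes[:-1], lengths):
            b.length = float(t)
        return Tree(nodes)

    def with_foreground(self, branch_name: str) -> "Tree":
        """Return a copy with exactly this branch tagged foreground (#1)."""
        nodes = [Branch(b.name, b.parent, b.length, 0, b.leaf_taxon) for b in self.nodes]
        hit = False
        for b in nodes[:-1]:
            if b.name == branch_name:
                b.tag, hit = 1, True
        if not hit:
            raise ValueError(f"no branch named {branch_name!r}")
        return Tree(nodes)

    def tags(self) -> np.ndarray:
        return np.array([b.tag for b in self.nodes[:-1]], dtype=int)

    # ----------------------------------------------------------- parsing

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        newick = _HASH_AFTER_LENGTH_RE.sub(r"__TAG\2__:\1", newick)
        newick = _HASH_RE.sub(lambda m: f"__TAG{m.group(1)}__", newick)
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        order = list(dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(order)}
        nodes: list[Branch] = []
        n_internal = 0
        for i, n in enumerate(order):
            parent = index[id(n.parent_node)] if n.parent_node is not None else -1
            label = n.taxon.label if n.taxon is not None else (n.label or "")
            tag = 0
            m = _TAG_RE.search(label)
            if m:
                tag = int(m.group(1) or m.group(2))
                label = label[: m.start()]
            if n.is_leaf():
                name, leaf = label, label
            else:
                name, leaf = f"node{n_internal}", None
                n_internal += 1
            length = n.edge.length if n.edge.length is not None else 0.0
            nodes.append(Branch(name, parent, float(length), tag, leaf))
        return cls(nodes)

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i, b in enumerate(self.nodes[:-1]):
            children.setdefault(b.parent, []).append(i)

        def render(i: int) -> str:
            b = self.nodes[i]
            tag = f" #{b.tag}" if b.tag else ""
            if b.leaf_taxon is not None:
                core = b.leaf_taxon
            else:
                core = "(" + ",".join(render(c) for c in children[i]) + ")"
            if b.parent == -1:
                return core
            return f"{core}{tag}:{b.length:g}"

        root = len(self.nodes) - 1
        return render(root) + ";"


def star_tree(taxa: list[str], branch_length: float = 0.1) -> Tree:
    """Completely unresolved star phylogeny over the given taxa."""
    nodes = [
        Branch(t, len(taxa), branch_length, 0, t) for t in taxa
    ] + [Branch("node0", -1, 0.0, 0, None)]
    return Tree(nodes)


def balanced_tree(taxa: list[str], branch_length: float = 0.1) -> Tree:
    """Balanced resolved topology over the taxa, equal branch lengths.

    Convenience for candidate-gene site analyses and simulations that need
    a resolved multi-taxon phylogeny.
    """
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    nodes = [f"{t}:{branch_length:g}" for t in taxa]
    while len(nodes) > 2:
        merged = []
        for i in range(0, len(nodes) - 1, 2):
            merged.append(f"({nodes[i]},{nodes[i + 1]}):{branch_length:g}")
        if len(nodes) % 2:
            merged.append(nodes[-1])
        nodes = merged
    return Tree.from_newick("(" + ",".join(nodes) + ");")


def read_tree(path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


def write_tree(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
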