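"""Rooted trees with branch lengths: Newick I/O and traversal helpers.

Parsing is delegated to dendropy; the comparative algorithms operate on a
minimal node structure (children lists, parent pointers, branch lengths in
time units).  Trees must be rooted, with unique tip labels and a positive
branch length on every non-root node.  Polytomies are rejected by default;
an explicit policy can resolve them into a caterpillar of zero-length
branches (flagged, and substituted by a tiny positive length where an
algorithm needs strictly positive variances).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, List, Optional, Union

import dendropy

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with named tips and branch lengths."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        labels = [t.label for t in self.tips()]
        if any(lbl is None for lbl in labels):
            raise TreeError("all tips must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    def tips(self) -> List[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> List[str]:
        return [t.label for t in self.tips()]

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_tip
        )

    def depth(self) -> float:
        """Maximum root-to-tip path length."""

        def walk(node: TreeNode, acc: float) -> float:
            acc += node.length or 0.0
            if node.is_tip:
                return acc
            return max(walk(c, acc) for c in node.children)

        return walk(self.root, 0.0)

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))


def _from_dendropy(node: "dendropy.Node", is_root: bool) -> TreeNode:
    label = None
    if node.taxon is not None:
        label = node.taxon.label.replace(" ", "_")
    elif node.label:
        label = node.label
    length = node.edge.length
    if not is_root:
        if length is None:
            raise TreeError(f"missing branch length above node {label or '<internal>'}")
        if length <= 0:
            raise TreeError(
                f"non-positive branch length ({length}) above node "
                f"{label or '<internal>'}"
            )
    out = TreeNode(label=label, length=length if not is_root else None)
    for child in node.child_nodes():
        out.add_child(_from_dendropy(child, is_root=False))
    return out


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Resolve polytomies into a caterpillar of zero-length branches.

    Zero lengths are kept as markers; algorithms needing positive variances
    substitute 1e-8 of tree depth.  A warning is logged per polytomy.
    """
    tree = tree.copy()
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            logger.warning(
                "resolving polytomy of degree %d at %s",
                len(node.children),
                node.label or "<internal>",
            )
            a = node.children.pop()
            b = node.children.pop()
            joint = TreeNode(label=None, length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    return tree


def read_newick(
    source: Union[str, Path], polytomy: str = "error"
) -> PhyloTree:
    """Parse a rooted Newick tree with mandatory branch lengths.

    ``source`` is a Newick string or a path.  ``polytomy`` is ``"error"``
    (default) or ``"resolve"``.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node, is_root=True)
    tree = PhyloTree(root)
    if not tree.is_binary():
        if polytomy == "error":
            raise TreeError(
                "tree contains polytomies (use polytomy='resolve' to "
                "resolve them into zero-length caterpillars)"
            )
        if polytomy == "resolve":
            tree = resolve_polytomies(tree)
        else:
            raise TreeError(f"unknown polytomy policy {polytomy!r}")
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths at 10 significant digits."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(tree.root) + ";"
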