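"""Rooted, bifurcating, time-scaled lineage trees.

Node times run forward: the root has the smallest time and all tips are
contemporaneous (sampled at the end of the experiment).  Branch lengths
are ``child.time - parent.time`` in absolute time units; an optional
per-branch rate multiplier supports externally supplied relaxed-clock
rates (multipliers are fixed inputs, never estimated here).
"""

from __future__ import annotations

import io
from typing import Callable, Iterator

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "time", "children", "parent", "rate_multiplier")

    def __init__(self, label: str | None = None, time: float = 0.0,
                 rate_multiplier: float = 1.0):
        self.label = label
        self.time = float(time)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.rate_multiplier = float(rate_multiplier)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.time - self.parent.time

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r}, t={self.time:.4g})"


class LineageTree:
    """A strictly bifurcating time tree with labelled, contemporaneous tips."""

    def __init__(self, root: Node, origin_time: float | None = None):
        self.root = root
        #: optional time of the process origin (a stem branch above the root)
        self.origin_time = origin_time
        self.validate()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def tip_time(self) -> float:
        return self.leaves()[0].time

    @property
    def height(self) -> float:
        return self.tip_time - self.root.time

    def validate(self) -> None:
        times = []
        for node in self.postorder():
            if node.children and len(node.children) != 2:
                raise TreeError(f"non-bifurcating node with {len(node.children)} children")
            if node.parent is not None and node.time < node.parent.time - 1e-9:
                raise TreeError("negative branch length")
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("unlabelled tip")
                times.append(node.time)
        if times and max(times) - min(times) > 1e-6 * max(1.0, abs(max(times))):
            raise TreeError("tips are not contemporaneous")
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        if self.origin_time is not None and self.origin_time > self.root.time + 1e-12:
            raise TreeError("origin must predate the root")

    # -- derived quantities ------------------------------------------------

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> frozenset of tip labels below it."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])
            else:
                s: frozenset[str] = frozenset()
                for c in node.children:
                    s |= out[id(c)]
                out[id(node)] = s
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable topology identifier: the set of internal clades."""
        sets = self.clade_leafsets()
        return frozenset(sets[id(n)] for n in self.internal_nodes())

    def copy(self) -> "LineageTree":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(node.label, node.time, node.rate_multiplier)
            mapping[id(node)] = clone
            for c in node.children:
                clone.add_child(mapping[id(c)])
        return LineageTree(mapping[id(self.root)], origin_time=self.origin_time)

    # -- Newick / Nexus I/O -------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            bl = f":{node.branch_length:.{precision}g}"
            if node.is_leaf:
                return f"{node.label}{bl}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){bl}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str, tip_time: float | None = None) -> "LineageTree":
        """Parse a Newick string (branch lengths in absolute time units).

        Node times are reconstructed from root-to-tip path lengths; if
        ``tip_time`` is given, all times are shifted so tips sit there.
        """
        dt = dendropy.Tree.get(data=text, schema="newick")
        root = Node(time=0.0)
        def build(dnode, pnode: Node) -> None:
            for child in dnode.child_nodes():
                bl = child.edge.length if child.edge.length is not None else 0.0
                label = child.taxon.label if child.taxon is not None else None
                node = Node(label=label, time=pnode.time + bl)
                pnode.add_child(node)
                build(child, node)
        build(dt.seed_node, root)
        tree = cls(root)
        if tip_time is not None:
            shift = tip_time - tree.tip_time
            for node in tree.postorder():
                node.time += shift
        return tree


def parse_tree_file(path: str) -> LineageTree:
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().lower().startswith("#nexus"):
        dt = dendropy.Tree.get(data=text, schema="nexus")
        return LineageTree.from_newick(dt.as_string(schema="newick").strip())
    return LineageTree.from_newick(text)


def trees_to_nexus(trees: list[LineageTree], names: list[str] | None = None) -> str:
    """Serialize a tree log as a minimal Nexus TREES block."""
    buf = io.StringIO()
    buf.write("#NEXUS\nBegin trees;\n")
    for i, tree in enumerate(trees):
        name = names[i] if names else f"STATE_{i}"
        buf.write(f"tree {name} = {tree.to_newick()}\n")
    buf.write("End;\n")
    return buf.getvalue()


def cherry(label_a: str, label_b: str, root_time: float, tip_time: float) -> LineageTree:
    """Convenience 2-tip tree."""
    root = Node(time=root_time)
    root.add_child(Node(label_a, tip_time))
    root.add_child(Node(label_b, tip_time))
    return LineageTree(root)
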