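"""Rooted-tree data model used by every stage of the pipeline.

Trees are rooted, possibly polytomous, with uniquely labeled leaves.  The
analyses are purely topological: branch lengths are carried (the simulator
sets them, and round-tripping preserves them) but no analysis stage reads
them except fossil sampling.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator


class TreeError(ValueError):
    """Structural problem with a tree (validation failure, bad lookup)."""


class Node:
    """A single tree node. Leaves carry a label; internals may."""

    __slots__ = ("id", "parent", "children", "label", "length", "orig_id")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.id: int = -1
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.length = length
        self.orig_id: int | None = None  # provenance link used by resolvers

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} {self.label!r}>"


class RootedTree:
    """A rooted tree over uniquely labeled leaves.

    Invariants (checked by :meth:`validate`): exactly one root; every
    non-root node has one parent; internal nodes have >= 2 children;
    leaves are labeled, labels unique.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._reindex()
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # construction helpers

    @classmethod
    def from_nested(cls, nested) -> "RootedTree":
        """Build from nested tuples/lists of leaf labels, e.g. ((\"A\",\"B\"),\"C\")."""

        def build(x) -> Node:
            if isinstance(x, (tuple, list)):
                node = Node()
                for c in x:
                    node.add_child(build(c))
                return node
            return Node(label=str(x))

        return cls(build(nested))

    def _reindex(self) -> None:
        self._nodes: list[Node] = []
        self._leaf_by_label: dict[str, Node] = {}
        for i, node in enumerate(_preorder(self.root)):
            node.id = i
            self._nodes.append(node)
            if node.is_leaf and node.label is not None:
                self._leaf_by_label.setdefault(node.label, node)

    # ------------------------------------------------------------------
    # basic queries

    @property
    def nodes(self) -> list[Node]:
        return self._nodes

    def preorder(self) -> Iterator[Node]:
        return _preorder(self.root)

    def postorder(self) -> Iterator[Node]:
        return _postorder(self.root)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self._nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self._leaf_by_label)

    def __len__(self) -> int:
        return len(self.leaves)

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self._nodes if not n.is_leaf)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise TreeError(f"unknown leaf label: {label!r}") from None

    def validate(self) -> None:
        seen: set[int] = set()
        labels: set[str] = set()
        for node in _preorder(self.root):
            if id(node) in seen:
                raise TreeError("cycle or shared node detected")
            seen.add(id(node))
            if node is not self.root and node.parent is None:
                raise TreeError("non-root node without a parent")
            for c in node.children:
                if c.parent is not node:
                    raise TreeError("child/parent pointers inconsistent")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled leaf")
                if node.label in labels:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                labels.add(node.label)
            elif len(node.children) < 2 and node is not self.root:
                raise TreeError("internal node with a single child")
        if not self.root.is_leaf and len(self.root.children) < 2:
            raise TreeError("root with a single child")

    # ------------------------------------------------------------------
    # clades

    def clade(self, node: Node) -> frozenset[str]:
        """Leaf-label set subtended by ``node``."""
        return frozenset(l.label for l in _preorder(node) if l.is_leaf)

    def clades(self, include_leaves: bool = False) -> set[frozenset[str]]:
        """All clades (leaf-label sets of internal nodes; root included)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
                if include_leaves:
                    out.add(below[id(node)])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = cl
                out.add(cl)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        labels = list(labels)
        if not labels:
            raise TreeError("mrca of an empty label set")
        paths = []
        for lab in labels:
            node: Node | None = self.leaf(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        assert mrca is not None
        return mrca

    def isomorphic(self, other: "RootedTree") -> bool:
        """Topological identity on labeled rooted trees: equal clade sets."""
        return (
            self.label_set == other.label_set
            and self.clades() == other.clades()
        )

    # ------------------------------------------------------------------
    # surgery (all return new trees; originals untouched)

    def copy(self) -> "RootedTree":
        return RootedTree(_copy_subtree(self.root), validate=False)

    def restrict(self, labels: Iterable[str], validate: bool = True) -> "RootedTree":
        """Induced subtree on a leaf-label subset, unary nodes suppressed."""
        keep = set(labels)
        missing = keep - set(self._leaf_by_label)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        root = _copy_subtree(self.root)
        root = _restrict(root, keep)
        if root is None:
            raise TreeError("restriction removed all leaves")
        root.parent = None
        root.length = None
        return RootedTree(root, validate=validate)

    def remove_leaf(self, label: str) -> "RootedTree":
        rest = self.label_set - {label}
        if label not in self.label_set:
            raise TreeError(f"unknown leaf label: {label!r}")
        if not rest:
            raise TreeError("cannot remove the only leaf")
        return self.restrict(rest)


def _preorder(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def _postorder(node: Node) -> Iterator[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return iter(reversed(out))


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, length=node.length)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


def _restrict(node: Node, keep: set[str]) -> Node | None:
    """Prune leaves not in ``keep``; splice unary chains, summing lengths."""
    if node.is_leaf:
        return node if node.label in keep else None
    kept = []
    for c in node.children:
        r = _restrict(c, keep)
        if r is not None:
            kept.append(r)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        if node.length is not None and child.length is not None:
            child.length = node.length + child.length
        elif node.length is not None:
            child.length = node.length
        return child
    node.children = []
    for c in kept:
        node.add_child(c)
    return node


def build_from_clades(
    labels: Iterable[str], clades: Iterable[frozenset[str]]
) -> RootedTree:
    """Assemble the tree whose internal nodes are exactly a compatible clade set.

    ``clades`` must be pairwise compatible (nested or disjoint); proper
    subsets of the full label set. Used to build consensus trees.
    """
    labels = sorted(set(labels))
    if len(labels) == 1:
        return RootedTree(Node(label=labels[0]))
    full = frozenset(labels)
    uniq = {c for c in clades if 1 < len(c) < len(full)}
    root = Node()
    holder: dict[frozenset[str], Node] = {full: root}
    # insert largest first so each clade's parent already exists
    for cl in sorted(uniq, key=len, reverse=True):
        parent = full
        for other in holder:
            if cl < other and len(other) < len(parent):
                parent = other
        if any(cl & other and not (cl <= other or other <= cl) for other in holder):
            raise TreeError("incompatible clade set")
        holder[parent].add_child(node := Node())
        holder[cl] = node
    for lab in labels:
        parent = full
        for cl in holder:
            if lab in cl and len(cl) < len(parent):
                parent = cl
        holder[parent].add_child(Node(label=lab))
    return RootedTree(root)
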