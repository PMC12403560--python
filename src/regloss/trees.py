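"""Rooted species trees for gain/loss inference.

Newick parsing is delegated to dendropy; the parsed tree is then frozen into
a light immutable structure with a reproducible child ordering (children are
sorted by their smallest descendant leaf label), so traversal order, branch
identifiers and every downstream output file are stable across runs.

A *branch* (edge) is identified by the node below it: :attr:`Node.branch_id`
is the sorted, ``"+"``-joined set of descendant leaf labels.  The branch
above the root stands for the stem lineage of the whole taxon set, so a
"gain at the root branch" means the character predates the in-group
diversification.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy


class TreeError(ValueError):
    """Raised for malformed or unusable species trees."""


class Node:
    """One node of a rooted species tree (the edge above it is "its" branch)."""

    __slots__ = ("label", "children", "parent", "leaves", "depth")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: "Node" | None = None
        self.leaves: frozenset[str] = frozenset()
        self.depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_id(self) -> str:
        return "+".join(sorted(self.leaves))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.branch_id})"


class SpeciesTree:
    """A rooted, leaf-labelled species tree.

    The root must be bifurcating (a trifurcating root is the classic
    signature of an unrooted tree and is rejected with advice to root it);
    polytomies below the root are permitted.
    """

    def __init__(self, root: Node):
        self.root = root
        self._finalize()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted error types
            if "Duplicate taxon labels" in str(exc):
                dup = str(exc).rsplit(":", 1)[-1].strip()
                raise TreeError(f"duplicate leaf label: {dup!r}") from exc
            raise TreeError(f"could not parse Newick: {exc}") from exc

        def convert(dnode) -> Node:
            children = dnode.child_nodes()
            if not children:
                label = dnode.taxon.label if dnode.taxon else dnode.label
                if not label:
                    raise TreeError("leaf without a label")
                return Node(str(label))
            node = Node()
            for ch in children:
                child = convert(ch)
                child.parent = node
                node.children.append(child)
            return node

        root = convert(dtree.seed_node)
        if len(root.children) == 1:
            raise TreeError("degenerate root with a single child")
        if len(root.children) > 2:
            raise TreeError(
                f"root has {len(root.children)} children; the tree appears "
                "unrooted — provide a rooted tree (bifurcating root)"
            )
        return cls(root)

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- serialisation --------------------------------------------------

    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(render(c) for c in node.children) + ")"

        return render(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structure ------------------------------------------------------

    def _finalize(self) -> None:
        def fill(node: Node) -> frozenset[str]:
            if node.is_leaf:
                node.leaves = frozenset([node.label])
            else:
                acc: set[str] = set()
                for child in node.children:
                    sub = fill(child)
                    if acc & sub:
                        dup = sorted(acc & sub)[0]
                        raise TreeError(f"duplicate leaf label: {dup!r}")
                    acc |= sub
                node.leaves = frozenset(acc)
                node.children.sort(key=lambda c: min(c.leaves))
            return node.leaves

        fill(self.root)
        self.root.depth = 0
        self._preorder: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            self._preorder.append(node)
            for child in reversed(node.children):
                child.depth = node.depth + 1
                stack.append(child)
        self._by_branch = {n.branch_id: n for n in self._preorder}
        self.taxa: tuple[str, ...] = tuple(
            n.label for n in self._preorder if n.is_leaf
        )

    # -- queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.taxa)

    def preorder(self) -> Iterator[Node]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._preorder)

    def node(self, branch_id: str) -> Node:
        try:
            return self._by_branch[branch_id]
        except KeyError:
            raise TreeError(f"no branch {branch_id!r} in tree") from None

    def leaf(self, label: str) -> Node:
        if label not in self.root.leaves:
            raise TreeError(f"taxon {label!r} not in tree")
        return self._by_branch[label]

    def lca(self, labels: Iterable[str]) -> Node:
        wanted = frozenset(labels)
        if not wanted:
            raise TreeError("LCA of an empty taxon set")
        missing = wanted - self.root.leaves
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        node = self.root
        while True:
            nxt = None
            for child in node.children:
                if wanted <= child.leaves:
                    nxt = child
                    break
            if nxt is None:
                return node
            node = nxt

    def is_ancestor_or_self(self, a: Node, b: Node) -> bool:
        """True if ``a`` is ``b`` or lies on the path from ``b`` to the root."""
        return b.leaves <= a.leaves
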