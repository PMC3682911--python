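"""Phylogenetic tree container used throughout the package.

A :class:`Tree` is a rooted node structure; unrooted semantics (internal
edges, NNI, bipartitions) are obtained by treating the root as a virtual
trifurcation.  Branch lengths are expected substitutions per site, supports
live on internal edges on a 0-100 scale.
"""
from __future__ import annotations

import io
from typing import Iterator, Optional, Sequence


class Node:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length: float = length
        self.label = label
        self.support: Optional[float] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length:g}>"


class TreeError(ValueError):
    pass


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def nodes(self) -> list[Node]:
        return list(self.postorder())

    def internal_edges(self) -> list[Node]:
        """Internal edges of the *unrooted* tree, each identified by its child
        node.  A root with two children is a virtual node sitting on a single
        unrooted edge: that edge is emitted once (via the first internal
        child) and only if both of its real endpoints are internal."""
        two_child_root = len(self.root.children) == 2
        edges = []
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            if two_child_root and n.parent is self.root:
                continue
            edges.append(n)
        if two_child_root:
            a, b = self.root.children
            if not a.is_leaf and not b.is_leaf:
                edges.append(a)
        return edges

    # ------------------------------------------------------------------ info
    def copy(self) -> "Tree":
        mapping: dict[int, Node] = {}

        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.support = n.support
            for c in n.children:
                m.add(rec(c))
            mapping[id(n)] = m
            return m

        t = Tree(rec(self.root))
        return t

    def leaf_set(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def mrca(self, labels: Sequence[str]) -> Node:
        want = set(labels)
        seen: dict[int, set] = {}
        best = None
        for n in self.postorder():
            s = {n.label} if n.is_leaf else set()
            for c in n.children:
                s |= seen.pop(id(c))
            seen[id(n)] = s
            if best is None and want <= s:
                best = n
        if best is None:
            missing = want - set(self.leaf_labels())
            raise TreeError(f"labels not on tree: {sorted(missing)}")
        return best

    # ------------------------------------------------------------ manipulation
    def suppress_unifurcations(self) -> None:
        for n in list(self.postorder()):
            if n is self.root or len(n.children) != 1:
                continue
            (c,) = n.children
            c.length += n.length
            p = n.parent
            i = p.children.index(n)
            p.children[i] = c
            c.parent = p
        while len(self.root.children) == 1 and self.root.children[0].children:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = 0.0

    def reroot_at(self, node: Node) -> None:
        """Make `node` the new root by reversing parent links on the path to
        the old root; suppresses the old root if it becomes degree-2.
        Edge lengths and supports travel with the edge (stored on whichever
        endpoint is the child after rerooting)."""
        if node is self.root:
            return
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        lengths = [n.length for n in path]
        supports = [n.support for n in path]
        for i in range(len(path) - 1):
            child, parent = path[i], path[i + 1]
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length = lengths[i]
            parent.support = supports[i]
        node.parent = None
        node.length = 0.0
        node.support = None
        self.root = node
        self.suppress_unifurcations()

    def deroot(self) -> None:
        """Collapse a bifurcating root into a trifurcation (unrooted form)."""
        r = self.root
        if len(r.children) != 2:
            return
        a, b = r.children
        gone = a if not a.is_leaf else b
        kept = b if gone is a else a
        if gone.is_leaf:
            return  # two-leaf tree, nothing to collapse
        kept.length += gone.length
        if kept.support is None:
            kept.support = gone.support
        r.children.remove(gone)
        for c in gone.children:
            r.children.append(c)
            c.parent = r

    def ladderize(self) -> None:
        order: dict[int, str] = {}
        for n in self.postorder():
            if n.is_leaf:
                order[id(n)] = n.label
            else:
                n.children.sort(key=lambda c: order[id(c)])
                order[id(n)] = order[id(n.children[0])]

    # ------------------------------------------------------------------ newick
    def newick(self, decimals: int = 6, support_decimals: int = 0,
               lengths: bool = True) -> str:
        buf = io.StringIO()

        def fmt_support(s: float) -> str:
            if support_decimals == 0:
                return str(int(round(s)))
            return f"{s:.{support_decimals}f}"

        def rec(n: Node) -> None:
            if n.children:
                buf.write("(")
                for i, c in enumerate(n.children):
                    if i:
                        buf.write(",")
                    rec(c)
                buf.write(")")
                if n.support is not None and n is not self.root:
                    buf.write(fmt_support(n.support))
                elif n.label:
                    buf.write(_quote(n.label))
            else:
                buf.write(_quote(n.label or ""))
            if lengths and n is not self.root:
                buf.write(f":{n.length:.{decimals}f}")

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    def canonical_newick(self, decimals: int = 6, **kw) -> str:
        t = self.copy()
        t.ladderize()
        return t.newick(decimals=decimals, **kw)

    def __len__(self) -> int:
        return len(self.leaves())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {len(self)} leaves>"

    # ---------------------------------------------------------------- queries
    def bipartitions(self) -> dict[int, frozenset]:
        """Map id(child-node) -> leaf set below that edge, for internal edges
        of the rooted tree (excluding root and leaves)."""
        sets: dict[int, frozenset] = {}
        cache: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                cache[id(n)] = frozenset([n.label])
            else:
                s = frozenset().union(*(cache[id(c)] for c in n.children))
                cache[id(n)] = s
                if n is not self.root:
                    sets[id(n)] = s
        return sets

    def unrooted_splits(self, nontrivial: bool = True) -> set[frozenset]:
        """Set of unrooted bipartitions, each as the smaller-side frozenset
        (ties broken lexicographically) -- used for RF-style comparisons."""
        all_leaves = frozenset(self.leaf_labels())
        out = set()
        for s in self.bipartitions().values():
            if nontrivial and (len(s) < 2 or len(all_leaves - s) < 2):
                continue
            comp = all_leaves - s
            pick = min((s, comp), key=lambda x: (len(x), sorted(x)))
            out.add(pick)
        return out


NEXUS_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789._-")


def _quote(label: str) -> str:
    if label and (set(label) <= NEXUS_SAFE):
        return label
    return "'" + label.replace("'", "''") + "'"


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted RF distance (symmetric difference of non-trivial splits)."""
    if set(t1.leaf_labels()) != set(t2.leaf_labels()):
        raise TreeError("trees must share one leaf set")
    s1, s2 = t1.unrooted_splits(), t2.unrooted_splits()
    return len(s1 ^ s2)


def restrict_to(tree: Tree, keep: Sequence[str] | set) -> Tree:
    """Copy of `tree` pruned to the leaves in `keep` (path lengths of
    removed degree-2 nodes are summed)."""
    keep = set(keep)
    missing = keep - set(tree.leaf_labels())
    if missing:
        raise TreeError(f"labels not on tree: {sorted(missing)}")
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.postorder()):
            if n.is_leaf and n.label not in keep and n.parent is not None:
                n.parent.children.remove(n)
                changed = True
            elif not n.is_leaf and not n.children and n.parent is not None:
                n.parent.children.remove(n)
                changed = True
        t.suppress_unifurcations()
    return t


def star_with(labels: Sequence[str]) -> Tree:
    root = Node()
    for lab in labels:
        root.add(Node(lab, 1.0))
    return Tree(root)
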