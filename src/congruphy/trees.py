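"""Phylogenetic tree structure, Newick/NEXUS I/O, pruning, rooting, consensus.

Trees are stored as rooted node structures, but every congruence metric in
this package treats them as unrooted objects: quartets and bipartitions are
root-free, so rooting (on the outgroup *Didelphis* in the original study)
matters only for display and serialization.  Polytomies are allowed
throughout.  Branch lengths are carried along but ignored by all metrics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy


class TreeError(ValueError):
    """Invalid tree operation or malformed tree input."""


class NewickParseError(TreeError):
    """Raised when Newick/NEXUS tree text cannot be parsed."""


class TreeNode:
    """A node in a rooted tree. Leaves carry a label; edges an optional length."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class PhyloTree:
    """Rooted tree with uniquely labelled leaves; polytomies permitted."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if any(not lab for lab in labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root))

    # -- traversal -------------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf():
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf()]

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    def internal_nodes(self, exclude_root: bool = False) -> list[TreeNode]:
        out = [n for n in self.preorder() if not n.is_leaf()]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def has_branch_lengths(self) -> bool:
        return any(
            n.length is not None for n in self.postorder() if n is not self.root
        )

    def __str__(self) -> str:
        return write_tree(self)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A split of the leaf set into two blocks.

    ``block`` is the canonical side: the one *not* containing the reference
    leaf (the lexicographically smallest label in the tree), i.e. the "clade
    side" when the tree is rooted adjacent to that leaf.
    """

    block: frozenset
    leaves: frozenset

    @property
    def complement(self) -> frozenset:
        return self.leaves - self.block

    def __repr__(self) -> str:  # pragma: no cover
        return "Bipartition({%s | %s})" % (
            ",".join(sorted(self.block)),
            ",".join(sorted(self.complement)),
        )


def _leafset(node: TreeNode) -> frozenset:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


def split_blocks(t: PhyloTree) -> set[frozenset]:
    """Non-trivial unrooted splits as canonical frozensets.

    The canonical representation of a split is the block not containing the
    lexicographically smallest leaf; trivial splits (block size < 2 or
    > n - 2) are excluded.
    """
    labels = frozenset(t.leaf_labels)
    n = len(labels)
    if n < 4:
        return set()
    ref = min(labels)
    blocks: set[frozenset] = set()
    for node in t.postorder():
        if node.is_leaf() or node is t.root:
            continue
        clade = _leafset(node)
        block = labels - clade if ref in clade else clade
        if 2 <= len(block) <= n - 2:
            blocks.add(block)
    return blocks


def bipartition_set(t: PhyloTree) -> set[Bipartition]:
    """All non-trivial bipartitions of the (unrooted) tree."""
    labels = frozenset(t.leaf_labels)
    return {Bipartition(b, labels) for b in split_blocks(t)}


def rooted_clades(t: PhyloTree) -> set[frozenset]:
    """Non-trivial rooted clades (leaf sets below internal nodes, excluding
    the full set and singletons)."""
    labels = frozenset(t.leaf_labels)
    out = set()
    for node in t.postorder():
        if node.is_leaf():
            continue
        clade = _leafset(node)
        if 2 <= len(clade) < len(labels):
            out.add(clade)
    return out


# ---------------------------------------------------------------------------
# Newick / NEXUS I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dt: dendropy.Tree) -> PhyloTree:
    def rec(dn) -> TreeNode:
        if dn.is_leaf():
            if dn.taxon is None or not dn.taxon.label:
                raise NewickParseError("leaf with empty label")
            node = TreeNode(dn.taxon.label, dn.edge.length)
        else:
            node = TreeNode(dn.label, dn.edge.length)
            for c in dn.child_nodes():
                node.add_child(rec(c))
        return node

    root = rec(dt.seed_node)
    root.length = None
    try:
        return PhyloTree(root)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def parse_tree(text: str) -> PhyloTree:
    """Parse a single Newick tree.

    Internal node labels (e.g. support values) are retained but unused by the
    metrics.  Raises :class:`NewickParseError` on malformed input or
    duplicate/empty leaf labels.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except NewickParseError:
        raise
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dt)


def read_trees(source: str, schema: str = "nexus") -> list[PhyloTree]:
    """Read a multi-tree file (NEXUS TREES block by default, or newick)."""
    try:
        tl = dendropy.TreeList.get(
            data=source, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"cannot parse {schema} trees: {exc}") from exc
    return [_from_dendropy(t) for t in tl]


def _needs_quotes(label: str) -> bool:
    special = set(" ()[]{}/\\,;:=*'\"`<>")
    return any(ch in special for ch in label)


def _fmt_label(label: str) -> str:
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_tree(t: PhyloTree, lengths: bool | None = None) -> str:
    """Serialize to Newick with deterministic (lexicographic) child order.

    ``lengths=None`` writes branch lengths only when the tree carries any.
    """
    if lengths is None:
        lengths = t.has_branch_lengths()

    def min_leaf(node: TreeNode) -> str:
        return node.label if node.is_leaf() else min(min_leaf(c) for c in node.children)

    def rec(node: TreeNode) -> str:
        if node.is_leaf():
            s = _fmt_label(node.label)
        else:
            kids = sorted(node.children, key=min_leaf)
            s = "(" + ",".join(rec(c) for c in kids) + ")"
            if node.label:
                s += _fmt_label(str(node.label))
        if lengths and node.parent is not None:
            s += f":{node.length if node.length is not None else 0.0:g}"
        return s

    return rec(t.root) + ";"


def topology_key(t: PhyloTree) -> str:
    """Canonical topology-only string (for deduplicating equal trees)."""
    return write_tree(t, lengths=False)


# ---------------------------------------------------------------------------
# Pruning and rooting
# ---------------------------------------------------------------------------


def _add_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def prune(t: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep``, suppressing degree-2 nodes."""
    keep = set(keep)
    have = set(t.leaf_labels)
    missing = keep - have
    if missing:
        raise TreeError(f"taxa not in tree: {', '.join(sorted(missing))}")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf():
            if node.label in keep:
                return TreeNode(node.label, node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            child.length = _add_lengths(child.length, node.length)
            return child
        new = TreeNode(node.label, node.length)
        for k in kids:
            new.add_child(k)
        return new

    root = rec(t.root)
    if root is None:
        raise TreeError("pruning removed every leaf")
    root.length = None
    return PhyloTree(root)


def root_on_outgroup(t: PhyloTree, outgroup: str) -> PhyloTree:
    """Re-root so that ``outgroup`` is sister to everything else.

    The returned tree has a binary root whose first child is the outgroup
    leaf.  Used for display/serialization only; metrics are unrooted.
    """
    t = t.copy()
    leaf = next((n for n in t.postorder() if n.is_leaf() and n.label == outgroup), None)
    if leaf is None:
        raise TreeError(f"outgroup {outgroup!r} not in tree")
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot root a single-leaf tree")
    if parent is t.root and len(t.root.children) == 2:
        t.root.children.sort(key=lambda c: c is not leaf)
        return t  # already rooted on this edge

    # Path from the outgroup's parent up to the old root, to be reversed.
    path: list[TreeNode] = []
    node: TreeNode | None = parent
    while node is not None:
        path.append(node)
        node = node.parent
    orig_len = [n.length for n in path]

    parent.children.remove(leaf)
    for i in range(len(path) - 1):
        cur, up = path[i], path[i + 1]
        up.children.remove(cur)
        cur.children.append(up)
        up.parent = cur
        up.length = orig_len[i]  # old edge cur->up, now hung below cur
    # The old root may be left with a single child: suppress it.
    old_root = path[-1]
    if len(path) >= 2 and len(old_root.children) == 1:
        par = old_root.parent
        only = old_root.children[0]
        only.length = _add_lengths(only.length, old_root.length)
        only.parent = par
        par.children[par.children.index(old_root)] = only

    root = TreeNode()
    root.add_child(leaf)
    parent.length = 0.0 if t.has_branch_lengths() else None
    root.add_child(parent)
    return PhyloTree(root)


def prune_and_root(t: PhyloTree, keep: Iterable[str], outgroup: str) -> PhyloTree:
    """Prune to ``keep`` then root with ``outgroup`` sister to the rest."""
    keep = set(keep)
    if outgroup not in keep:
        raise TreeError(f"outgroup {outgroup!r} must be in the kept taxa")
    return root_on_outgroup(prune(t, keep), outgroup)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def tree_from_splits(blocks: Iterable[frozenset], leaves: Iterable[str]) -> PhyloTree:
    """Build the unique tree displaying a compatible set of canonical splits.

    ``blocks`` must be canonical (oriented away from the smallest leaf), so a
    compatible collection forms a laminar family and can be nested directly.
    """
    leaves = sorted(set(leaves))
    blocks = sorted(set(blocks), key=len, reverse=True)
    root = TreeNode()
    node_for: list[tuple[frozenset, TreeNode]] = []
    for b in blocks:
        parent = root
        for ob, onode in node_for:
            if b <= ob:
                parent = onode  # smallest container is found last (sorted desc)
        node = TreeNode()
        parent.add_child(node)
        node_for.append((b, node))
    for lab in leaves:
        parent = root
        for ob, onode in node_for:
            if lab in ob:
                parent = onode
        parent.add_child(TreeNode(lab))
    return PhyloTree(root)


def _consensus(trees: Sequence[PhyloTree], min_count: int) -> PhyloTree:
    if not trees:
        raise TreeError("consensus of an empty tree list")
    leafset = frozenset(trees[0].leaf_labels)
    counts: dict[frozenset, int] = {}
    for t in trees:
        if frozenset(t.leaf_labels) != leafset:
            raise TreeError("consensus requires identical leaf sets")
        for b in split_blocks(t):
            counts[b] = counts.get(b, 0) + 1
    kept = [b for b, c in counts.items() if c >= min_count]
    return tree_from_splits(kept, leafset)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree whose splits are exactly those present in every input tree."""
    return _consensus(trees, len(trees))


def majority_rule_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing the splits present in more than half of the inputs."""
    return _consensus(trees, len(trees) // 2 + 1)
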