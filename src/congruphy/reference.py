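"""Naive reference implementations used to validate the fast paths.

Everything here is deliberately simple and independent of the optimized
code: quartet classification via the four-point condition on path-length
distances, Fitch lengths by exhaustive enumeration of internal labelings,
and a plain random-tree generator.  These are the oracles the test suite
and the acceptance checks compare against; they are far too slow for real
analyses.
"""

from __future__ import annotations

import random
from itertools import combinations, product

from .characters import CharacterMatrix
from .trees import PhyloTree, TreeNode


def random_binary_tree(
    labels: list[str], rng: random.Random, lengths: bool = False
) -> PhyloTree:
    """Uniform-ish random rooted binary tree by sequential random insertion."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    root = TreeNode()
    root.add_child(TreeNode(labels[0]))
    v = TreeNode()
    v.add_child(TreeNode(labels[1]))
    v.add_child(TreeNode(labels[2]))
    root.add_child(v)
    tree = PhyloTree(root)
    for lab in labels[3:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        edge = rng.choice(edges)
        p = edge.parent
        u = TreeNode()
        p.children[p.children.index(edge)] = u
        u.parent = p
        u.add_child(edge)
        u.add_child(TreeNode(lab))
    if lengths:
        for node in tree.postorder():
            if node.parent is not None:
                node.length = rng.uniform(0.05, 1.0)
    return tree


def _path_distances(t: PhyloTree) -> dict[str, dict[str, int]]:
    """Topological (unit-edge) leaf-to-leaf distances by traversal."""
    # adjacency over node ids
    adj: dict[int, list] = {}
    nodes = list(t.postorder())
    for n in nodes:
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append(c)
            adj.setdefault(id(c), []).append(n)
    leaves = [n for n in nodes if n.is_leaf()]
    out: dict[str, dict[str, int]] = {}
    for leaf in leaves:
        dist = {id(leaf): 0}
        frontier = [leaf]
        while frontier:
            nxt = []
            for n in frontier:
                for m in adj[id(n)]:
                    if id(m) not in dist:
                        dist[id(m)] = dist[id(n)] + 1
                        nxt.append(m)
            frontier = nxt
        out[leaf.label] = {l.label: dist[id(l)] for l in leaves}
    return out


def quartet_topology_bruteforce(dists, a: str, b: str, c: str, d: str) -> int:
    """0 = unresolved, 1 = ab|cd, 2 = ac|bd, 3 = ad|bc (four-point condition).

    With unit branch lengths the sum of within-pair distances is strictly
    smallest for the true split, and all three sums tie on a star.
    """
    s1 = dists[a][b] + dists[c][d]
    s2 = dists[a][c] + dists[b][d]
    s3 = dists[a][d] + dists[b][c]
    m = min(s1, s2, s3)
    winners = [s == m for s in (s1, s2, s3)]
    if sum(winners) != 1:
        return 0
    return winners.index(True) + 1


def quartet_counts_bruteforce(t1: PhyloTree, t2: PhyloTree) -> tuple[int, ...]:
    """(Q, s, d, r1, r2, u) by direct enumeration of every quartet."""
    leaves = t1.leaf_labels
    assert leaves == t2.leaf_labels
    d1, d2 = _path_distances(t1), _path_distances(t2)
    Q = s = d = r1 = r2 = u = 0
    for a, b, c, e in combinations(leaves, 4):
        Q += 1
        q1 = quartet_topology_bruteforce(d1, a, b, c, e)
        q2 = quartet_topology_bruteforce(d2, a, b, c, e)
        if q1 and q2:
            if q1 == q2:
                s += 1
            else:
                d += 1
        elif q1:
            r1 += 1
        elif q2:
            r2 += 1
        else:
            u += 1
    return Q, s, d, r1, r2, u


def fitch_length_bruteforce(t: PhyloTree, m: CharacterMatrix, col: int) -> int:
    """Minimum changes for one column by enumerating all internal labelings."""
    states: set[str] = set()
    for row in m.cells:
        cell = row[col]
        if isinstance(cell, frozenset):
            states |= cell
    if not states:
        return 0
    alphabet = sorted(states)
    internals = [n for n in t.postorder() if not n.is_leaf()]
    leaf_sets = {}
    for leaf in t.leaves():
        cell = m.cells[m.taxon_index(leaf.label)][col]
        leaf_sets[id(leaf)] = sorted(cell) if isinstance(cell, frozenset) else alphabet
    best = None
    for assignment in product(alphabet, repeat=len(internals)):
        lab = {id(n): a for n, a in zip(internals, assignment)}
        total = 0
        ok = True
        for node in t.postorder():
            if node.parent is None:
                continue
            if node.is_leaf():
                # leaf may take any of its allowed states: choose the best
                if lab[id(node.parent)] not in leaf_sets[id(node)]:
                    total += 1
            else:
                total += lab[id(node)] != lab[id(node.parent)]
            if best is not None and total >= best:
                ok = False
                break
        if ok and (best is None or total < best):
            best = total
    return best or 0
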