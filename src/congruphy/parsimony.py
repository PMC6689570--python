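"""Parsimony engine: Fitch scoring, implied weights, heuristic/exhaustive MP
search, acctran/deltran ancestral states, and hypothetical-ancestor export.

Scoring uses bitmask state sets vectorized over characters with numpy, so a
full-tree Fitch pass costs a handful of array operations per node regardless
of how many characters the matrix holds.  Missing and inapplicable cells
contribute the full column alphabet.  On polytomies the downpass combines
children by iterated pairwise intersection/union (the classical Fitch rule
applied left to right); an exact minimum under unit costs is available via
the dynamic-programming reconstruction path and the ``exact=True`` switch of
:func:`fitch_length`.

Ancestral-state reconstruction runs an exact unit-cost dynamic programme
(correct on polytomies as well), then resolves each internal node under
accelerated (acctran: prefer a change on the branch entering the node when a
most-parsimonious reconstruction allows one) or delayed (deltran: keep the
parental state whenever possible) transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .characters import (
    DNA,
    INAPPLICABLE,
    MISSING,
    MORPHOLOGY,
    CharacterMatrix,
    MatrixError,
)
from .trees import PhyloTree, TreeNode, strict_consensus, topology_key

_BIG = np.int32(1 << 20)


class ParsimonyError(ValueError):
    """Invalid input to a parsimony operation."""


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


@dataclass
class EncodedMatrix:
    """Bitmask encoding of a character matrix for fast Fitch passes."""

    taxa: list[str]
    masks: np.ndarray  # (n_taxa, n_chars) uint32; missing = full alphabet
    alphabets: list[list[str]]  # symbol order per column
    full: np.ndarray  # (n_chars,) uint32 full-alphabet masks
    min_steps: np.ndarray  # (n_chars,) theoretical minimum steps

    @property
    def n_chars(self) -> int:
        return self.masks.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.masks[self.taxa.index(label)]


def encode_matrix(m: CharacterMatrix, taxa: Sequence[str] | None = None) -> EncodedMatrix:
    """Encode columns as bitmasks over each column's observed alphabet.

    ``taxa`` restricts (and orders) the rows; the per-column alphabet and the
    theoretical minimum step count are computed over that restriction.  The
    minimum counts one step per extra state observed unambiguously (singleton
    cells), the standard homoplasy baseline for unordered characters.
    """
    if taxa is None:
        taxa = list(m.taxa)
    rows = [m.cells[m.taxon_index(t)] for t in taxa]
    n_chars = m.n_chars
    masks = np.zeros((len(taxa), n_chars), dtype=np.uint32)
    alphabets: list[list[str]] = []
    full = np.zeros(n_chars, dtype=np.uint32)
    min_steps = np.zeros(n_chars, dtype=np.int32)
    for j in range(n_chars):
        states: set[str] = set()
        for row in rows:
            cell = row[j]
            if isinstance(cell, frozenset):
                states |= cell
        alpha = sorted(states) if states else ["0"]
        if len(alpha) > 32:
            raise ParsimonyError(f"column {j}: alphabet larger than 32 states")
        bit = {s: np.uint32(1 << i) for i, s in enumerate(alpha)}
        fmask = np.uint32((1 << len(alpha)) - 1)
        singles: set[str] = set()
        for i, row in enumerate(rows):
            cell = row[j]
            if isinstance(cell, frozenset):
                mk = np.uint32(0)
                for s in cell:
                    mk |= bit[s]
                masks[i, j] = mk
                if len(cell) == 1:
                    singles |= cell
            else:
                masks[i, j] = fmask
        alphabets.append(alpha)
        full[j] = fmask
        min_steps[j] = max(len(singles) - 1, 0)
    return EncodedMatrix(list(taxa), masks, alphabets, full, min_steps)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _fitch_per_char(tree: PhyloTree, enc: EncodedMatrix) -> np.ndarray:
    idx = {t: i for i, t in enumerate(enc.taxa)}
    steps = np.zeros(enc.n_chars, dtype=np.int32)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            try:
                masks[id(node)] = enc.masks[idx[node.label]]
            except KeyError:
                raise ParsimonyError(f"leaf {node.label!r} has no matrix row") from None
        else:
            kids = node.children
            acc = masks.pop(id(kids[0]))
            for c in kids[1:]:
                cm = masks.pop(id(c))
                inter = acc & cm
                empty = inter == 0
                steps += empty
                acc = np.where(empty, acc | cm, inter)
            masks[id(node)] = acc
    return steps


def fitch_length(
    t: PhyloTree, m: CharacterMatrix, exact: bool = False
) -> tuple[np.ndarray, int]:
    """Per-character minimum change counts and their total.

    With ``exact=True`` the unit-cost dynamic programme is used instead of
    the pairwise Fitch pass; the two agree on binary trees, and the DP is
    exact on polytomies too.
    """
    enc = encode_matrix(m, taxa=None)
    if exact:
        per_char = _sankoff_lengths(t, m)
    else:
        per_char = _fitch_per_char(t, enc)
    return per_char, int(per_char.sum())


def implied_weights_score(
    t: PhyloTree,
    m: CharacterMatrix,
    k: float,
    per_char: np.ndarray | None = None,
    min_steps: np.ndarray | None = None,
) -> float:
    """Goloboff-style concave fit: sum over characters of e / (e + k).

    ``e`` is the homoplasy excess — Fitch steps minus the character's
    theoretical minimum.  Lower is better; as k grows the induced tree
    ranking converges to the equal-weights ranking.
    """
    if k <= 0:
        raise ParsimonyError(f"concavity constant must be positive, got {k}")
    if per_char is None or min_steps is None:
        enc = encode_matrix(m)
        per_char = _fitch_per_char(t, enc)
        min_steps = enc.min_steps
    e = np.maximum(per_char - min_steps, 0).astype(float)
    return float(np.sum(e / (e + k)))


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------


class _Scorer:
    """Scores trees over a fixed taxon set; equal or implied weights."""

    def __init__(self, enc: EncodedMatrix, k: float | None):
        self.enc = enc
        self.k = k

    def score(self, tree: PhyloTree) -> float:
        per_char = _fitch_per_char(tree, self.enc)
        if self.k is None:
            return float(per_char.sum())
        e = np.maximum(per_char - self.enc.min_steps, 0).astype(float)
        return float(np.sum(e / (e + self.k)))


def _three_taxon_tree(a: str, b: str, c: str) -> PhyloTree:
    root = TreeNode()
    root.add_child(TreeNode(a))
    v = TreeNode()
    v.add_child(TreeNode(b))
    v.add_child(TreeNode(c))
    root.add_child(v)
    return PhyloTree(root)


def _insertion_edges(tree: PhyloTree) -> list[TreeNode]:
    """Nodes whose parent edge is a distinct unrooted edge.

    With a binary root, the two root-child edges are the same unrooted edge,
    so one of them is skipped.
    """
    skip = tree.root.children[1] if len(tree.root.children) == 2 else None
    return [n for n in tree.postorder() if n.parent is not None and n is not skip]


def _insert_leaf(edge_node: TreeNode, leaf: TreeNode) -> TreeNode:
    p = edge_node.parent
    u = TreeNode()
    p.children[p.children.index(edge_node)] = u
    u.parent = p
    u.children = [edge_node, leaf]
    edge_node.parent = u
    leaf.parent = u
    return u


def _remove_inserted(u: TreeNode) -> None:
    edge_node = u.children[0]
    p = u.parent
    p.children[p.children.index(u)] = edge_node
    edge_node.parent = p


def _nni_moves(tree: PhyloTree) -> list[tuple[TreeNode, int, TreeNode, int]]:
    """NNI swaps as (parent_a, index_a, parent_b, index_b) child exchanges."""
    moves = []
    root = tree.root
    for v in tree.preorder():
        if v.is_leaf() or v.parent is None:
            continue
        p = v.parent
        if p is root and len(root.children) == 2:
            if v is not root.children[0]:
                continue  # central edge handled once
            s = root.children[1]
            if s.is_leaf():
                continue  # pendant edge in the unrooted sense
            moves.append((v, 0, s, 0))
            moves.append((v, 1, s, 0))
        else:
            iv = p.children.index(v)
            js = 1 - iv
            moves.append((v, 0, p, js))
            moves.append((v, 1, p, js))
    return moves


def _apply_swap(move: tuple[TreeNode, int, TreeNode, int]) -> None:
    pa, ia, pb, ib = move
    a, b = pa.children[ia], pb.children[ib]
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _spr_regrafts(tree: PhyloTree) -> list[TreeNode]:
    return _insertion_edges(tree)


def _greedy_addition(
    taxa: list[str], scorer: _Scorer, rng: np.random.Generator
) -> PhyloTree:
    tree = _three_taxon_tree(*taxa[:3])
    for label in taxa[3:]:
        leaf = TreeNode(label)
        best: list[TreeNode] = []
        best_score = None
        for edge in _insertion_edges(tree):
            u = _insert_leaf(edge, leaf)
            s = scorer.score(tree)
            _remove_inserted(u)
            if best_score is None or s < best_score - 1e-9:
                best_score, best = s, [edge]
            elif s <= best_score + 1e-9:
                best.append(edge)
        choice = best[int(rng.integers(len(best)))]
        _insert_leaf(choice, leaf)
    return tree


def _hill_climb_nni(
    tree: PhyloTree, scorer: _Scorer
) -> tuple[PhyloTree, float]:
    """Steepest-descent NNI to a local optimum."""
    score = scorer.score(tree)
    improved = True
    while improved:
        improved = False
        best_move = None
        best_score = score
        for move in _nni_moves(tree):
            _apply_swap(move)
            s = scorer.score(tree)
            if s < best_score - 1e-9:
                best_score, best_move = s, move
            _apply_swap(move)
        if best_move is not None:
            _apply_swap(best_move)
            score = best_score
            improved = True
    return tree, score


def _collect_tied_neighbors(
    tree: PhyloTree, scorer: _Scorer, score: float, cap: int
) -> dict[str, PhyloTree]:
    """NNI neighbors of a local optimum with the same score (co-optima)."""
    ties: dict[str, PhyloTree] = {}
    for move in _nni_moves(tree):
        if len(ties) >= cap:
            break
        _apply_swap(move)
        if abs(scorer.score(tree) - score) <= 1e-9:
            key = topology_key(tree)
            if key not in ties:
                ties[key] = tree.copy()
        _apply_swap(move)
    return ties


def _spr_round(
    tree: PhyloTree, scorer: _Scorer, score: float
) -> tuple[PhyloTree, float, bool]:
    """One pass of subtree pruning-regrafting; returns improvement flag."""
    for node in list(tree.preorder()):
        if node.parent is None or node.parent is tree.root:
            continue
        p = node.parent
        gp = p.parent
        sib = p.children[1 - p.children.index(node)]
        # prune: replace p with sibling
        gp.children[gp.children.index(p)] = sib
        sib.parent = gp
        improved_here = False
        for edge in _insertion_edges(tree):
            if edge is node or edge is sib:
                continue
            u = _insert_leaf(edge, node)
            s = scorer.score(tree)
            if s < score - 1e-9:
                score = s
                improved_here = True
                break
            _remove_inserted(u)
        if improved_here:
            return tree, score, True
        # restore original attachment
        gp.children[gp.children.index(sib)] = p
        p.parent = gp
        sib.parent = p
        node.parent = p
    return tree, score, False


def _enumerate_unrooted(taxa: Sequence[str]):
    """Yield every unrooted topology on the taxa (as rooted binary trees)."""
    tree = _three_taxon_tree(*taxa[:3])

    def rec(i: int):
        if i == len(taxa):
            yield tree
            return
        leaf = TreeNode(taxa[i])
        for edge in list(_insertion_edges(tree)):
            u = _insert_leaf(edge, leaf)
            yield from rec(i + 1)
            _remove_inserted(u)

    yield from rec(3)


@dataclass
class SearchResult:
    """Outcome of an MP search: all retained co-optimal trees + consensus."""

    trees: list[PhyloTree]
    score: float
    settings: dict
    consensus: PhyloTree = field(init=False)

    def __post_init__(self) -> None:
        self.consensus = (
            self.trees[0].copy() if len(self.trees) == 1 else strict_consensus(self.trees)
        )

    def to_nexus(self) -> str:
        """TREES block of all retained optima plus their strict consensus."""
        from .trees import write_tree

        lines = ["#NEXUS", "", "BEGIN TREES;"]
        for i, t in enumerate(self.trees, 1):
            lines.append(f"    TREE optimum_{i} = {write_tree(t, lengths=False)}")
        lines.append(f"    TREE strict_consensus = {write_tree(self.consensus, lengths=False)}")
        lines.append("END;")
        return "\n".join(lines) + "\n"

    def metadata(self) -> dict:
        """JSON-serializable search metadata."""
        return {"score": self.score, "n_trees": len(self.trees), **self.settings}


def mp_search(
    m: CharacterMatrix,
    weights: str | float = "equal",
    replicates: int = 10,
    seed: int | np.random.Generator = 0,
    taxa: Sequence[str] | None = None,
    method: str = "auto",
    swap: str = "nni",
    max_trees: int = 10_000,
    tie_neighbors: int = 50,
    exhaustive_cutoff: int = 8,
) -> SearchResult:
    """Maximum-parsimony search.

    ``weights='equal'`` minimizes total Fitch steps; a number is interpreted
    as the implied-weighting concavity constant k.  ``method='exhaustive'``
    (automatic at <= ``exhaustive_cutoff`` taxa) scores every unrooted
    topology and returns the full optimum set; the heuristic uses
    random-addition-sequence starting trees followed by NNI hill climbing,
    optionally with SPR rounds (``swap='spr'``).  Deterministic given
    ``seed``.  All-missing taxa are retained (they join the consensus as
    unresolved placements).
    """
    if taxa is None:
        taxa = list(m.taxa)
    if len(taxa) < 4:
        raise ParsimonyError("MP search needs at least 4 taxa")
    k = None if weights == "equal" else float(weights)
    if k is not None and k <= 0:
        raise ParsimonyError("concavity constant must be positive")
    enc = encode_matrix(m, taxa=taxa)
    scorer = _Scorer(enc, k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    settings = {
        "weights": "equal" if k is None else f"implied(k={k:g})",
        "replicates": replicates,
        "swap": swap,
        "method": method,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
    }

    if method == "exhaustive" or (method == "auto" and len(taxa) <= exhaustive_cutoff):
        best_score = None
        best: dict[str, PhyloTree] = {}
        for tree in _enumerate_unrooted(list(taxa)):
            s = scorer.score(tree)
            if best_score is None or s < best_score - 1e-9:
                best_score = s
                best = {topology_key(tree): tree.copy()}
            elif s <= best_score + 1e-9 and len(best) < max_trees:
                best.setdefault(topology_key(tree), tree.copy())
        settings["method"] = "exhaustive"
        return SearchResult(list(best.values()), best_score, settings)

    if method not in ("auto", "heuristic"):
        raise ParsimonyError(f"unknown search method {method!r}")
    settings["method"] = "heuristic"
    pool: dict[str, PhyloTree] = {}
    pool_scores: dict[str, float] = {}
    for _ in range(replicates):
        order = list(taxa)
        perm = rng.permutation(len(order))
        order = [order[i] for i in perm]
        tree = _greedy_addition(order, scorer, rng)
        tree, score = _hill_climb_nni(tree, scorer)
        if swap == "spr":
            improved = True
            while improved:
                tree, score, improved = _spr_round(tree, scorer, score)
                if improved:
                    tree, score = _hill_climb_nni(tree, scorer)
        key = topology_key(tree)
        pool[key] = tree.copy()
        pool_scores[key] = score
        for tk, tt in _collect_tied_neighbors(tree, scorer, score, tie_neighbors).items():
            if tk not in pool and len(pool) < max_trees:
                pool[tk] = tt
                pool_scores[tk] = score
    best_score = min(pool_scores.values())
    best = [pool[kk] for kk, s in pool_scores.items() if s <= best_score + 1e-9]
    return SearchResult(best[:max_trees], best_score, settings)


# ---------------------------------------------------------------------------
# Ancestral-state reconstruction (exact unit-cost DP)
# ---------------------------------------------------------------------------


@dataclass
class CharacterReconstruction:
    """Per-internal-node character states under parsimony.

    Internal nodes are numbered in preorder starting at 1 (the root).  For
    each node, per character: the Fitch downpass set, the MPR set (states
    attained in at least one most-parsimonious reconstruction), and the
    resolution set plus single tie-broken state under acctran and deltran.
    ``per_char_steps`` is the exact minimum change count.
    """

    node_ids: list[int]
    alphabets: list[list[str]]
    downpass: dict[int, list[frozenset]]
    mpr: dict[int, list[frozenset]]
    acctran_sets: dict[int, list[frozenset]]
    deltran_sets: dict[int, list[frozenset]]
    acctran_states: dict[int, list[str]]
    deltran_states: dict[int, list[str]]
    per_char_steps: np.ndarray
    total_steps: int

    def implied_changes(self, tree: PhyloTree, mode: str) -> int:
        """Count state changes implied by the mode's resolved states."""
        states = self.acctran_states if mode == "acctran" else self.deltran_states
        node_num = _number_internal(tree)
        leaf_state: dict[str, list[str]] = getattr(self, "_leaf_states")
        changes = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = states[node_num[id(node.parent)]]
            cs = leaf_state[node.label] if node.is_leaf() else states[node_num[id(node)]]
            for j in range(len(ps)):
                if cs[j] is not None and cs[j] != ps[j]:
                    changes += 1
        return changes


def _number_internal(tree: PhyloTree) -> dict[int, int]:
    num = {}
    i = 0
    for node in tree.preorder():
        if not node.is_leaf():
            i += 1
            num[id(node)] = i
    return num


def _sankoff_costs(tree: PhyloTree, enc: EncodedMatrix):
    """Exact unit-cost DP over (characters x states); returns cost tables."""
    n_chars = enc.n_chars
    S = max(len(a) for a in enc.alphabets)
    valid = np.full((n_chars, S), False)
    for j, a in enumerate(enc.alphabets):
        valid[j, : len(a)] = True
    idx = {t: i for i, t in enumerate(enc.taxa)}
    down: dict[int, np.ndarray] = {}
    bits = (enc.masks[:, :, None] >> np.arange(S, dtype=np.uint32)[None, None, :]) & 1

    for node in tree.postorder():
        if node.is_leaf():
            allowed = bits[idx[node.label]].astype(bool)
            c = np.where(allowed & valid, 0, _BIG).astype(np.int32)
        else:
            c = np.zeros((n_chars, S), dtype=np.int32)
            for child in node.children:
                cc = down[id(child)]
                contrib = np.minimum(cc, cc.min(axis=1, keepdims=True) + 1)
                c = c + contrib
            c[~valid] = _BIG
        down[id(node)] = np.minimum(c, _BIG)
    return down, valid, S


def reconstruct_ancestral_states(
    t: PhyloTree, m: CharacterMatrix, mode: str = "both"
) -> CharacterReconstruction:
    """Most-parsimonious ancestral states at every internal node.

    The tree must be rooted (its root is node 1); polytomies are handled
    exactly by the unit-cost dynamic programme.  At the root the resolved
    state is the lexicographically smallest optimum under both modes; below
    it, deltran keeps the parental state whenever a most-parsimonious
    reconstruction allows it, while acctran prefers a change on the entering
    branch when one is available at no extra cost.
    """
    if mode not in ("acctran", "deltran", "both"):
        raise ParsimonyError(f"unknown mode {mode!r}")
    if t.root is None or len(t.root.children) < 2:
        raise ParsimonyError("ancestral reconstruction requires a rooted tree")
    enc = encode_matrix(m, taxa=t.leaf_labels)
    down, valid, S = _sankoff_costs(t, enc)
    n_chars = enc.n_chars
    root_cost = down[id(t.root)]
    per_char_steps = root_cost.min(axis=1).astype(np.int32)
    total = int(per_char_steps.sum())

    # "Outside" costs for unconditional MPR sets: up[v][x] = best cost of the
    # rest of the tree given node v takes state x.
    up: dict[int, np.ndarray] = {id(t.root): np.where(valid, 0, _BIG).astype(np.int32)}
    for node in t.preorder():
        if node.is_leaf():
            continue
        c_up = up[id(node)]
        kids = node.children
        contribs = []
        for child in kids:
            cc = down[id(child)]
            contribs.append(np.minimum(cc, cc.min(axis=1, keepdims=True) + 1))
        total_contrib = np.sum(contribs, axis=0)
        for child, contrib in zip(kids, contribs):
            other = c_up + total_contrib - contrib
            child_up = np.minimum(other, other.min(axis=1, keepdims=True) + 1)
            child_up[~valid] = _BIG
            up[id(child)] = np.minimum(child_up, _BIG)

    node_num = _number_internal(t)
    state_idx = np.arange(S)

    def mask_to_sets(bool_arr: np.ndarray, j_alpha) -> list[frozenset]:
        return [
            frozenset(j_alpha[jj][kk] for kk in np.nonzero(bool_arr[jj])[0])
            for jj in range(n_chars)
        ]

    downpass: dict[int, list[frozenset]] = {}
    mpr: dict[int, list[frozenset]] = {}
    acc_sets: dict[int, list[frozenset]] = {}
    del_sets: dict[int, list[frozenset]] = {}
    acc_states: dict[int, list[str]] = {}
    del_states: dict[int, list[str]] = {}
    assigned_acc: dict[int, np.ndarray] = {}
    assigned_del: dict[int, np.ndarray] = {}

    for node in t.preorder():
        if node.is_leaf():
            continue
        nid = node_num[id(node)]
        c = down[id(node)]
        dmin = c.min(axis=1, keepdims=True)
        down_ok = c == dmin
        downpass[nid] = mask_to_sets(down_ok, enc.alphabets)
        marg = c + up[id(node)]
        mpr_ok = marg == marg.min(axis=1, keepdims=True)
        mpr[nid] = mask_to_sets(mpr_ok, enc.alphabets)

        if node is t.root:
            ok = down_ok
            first = np.argmax(ok, axis=1)
            acc_sets[nid] = del_sets[nid] = mask_to_sets(ok, enc.alphabets)
            assigned_acc[id(node)] = first.copy()
            assigned_del[id(node)] = first.copy()
        else:
            for tag, assigned, out_sets in (
                ("acc", assigned_acc, acc_sets),
                ("del", assigned_del, del_sets),
            ):
                p_state = assigned[id(node.parent)]
                cond = c + (state_idx[None, :] != p_state[:, None])
                ok = cond == cond.min(axis=1, keepdims=True)
                p_in = ok[np.arange(n_chars), p_state]
                if tag == "del":
                    sel = ok.copy()
                    sel[p_in] = False
                    sel[p_in, p_state[p_in]] = True
                else:
                    sel = ok.copy()
                    sel[np.arange(n_chars), p_state] = False
                    none_left = ~sel.any(axis=1)
                    sel[none_left] = ok[none_left]
                out_sets[nid] = mask_to_sets(sel, enc.alphabets)
                assigned[id(node)] = np.argmax(sel, axis=1)

        acc_states[nid] = [
            enc.alphabets[j][assigned_acc[id(node)][j]] for j in range(n_chars)
        ]
        del_states[nid] = [
            enc.alphabets[j][assigned_del[id(node)][j]] for j in range(n_chars)
        ]

    recon = CharacterReconstruction(
        node_ids=sorted(node_num.values()),
        alphabets=enc.alphabets,
        downpass=downpass,
        mpr=mpr,
        acctran_sets=acc_sets,
        deltran_sets=del_sets,
        acctran_states=acc_states,
        deltran_states=del_states,
        per_char_steps=per_char_steps,
        total_steps=total,
    )
    # leaf resolved states for implied-change audits (None when ambiguous)
    leaf_states: dict[str, list[str | None]] = {}
    for leaf in t.leaves():
        row = m.cells[m.taxon_index(leaf.label)]
        leaf_states[leaf.label] = [
            next(iter(c)) if isinstance(c, frozenset) and len(c) == 1 else None
            for c in row
        ]
    object.__setattr__(recon, "_leaf_states", leaf_states)
    return recon


def _sankoff_lengths(t: PhyloTree, m: CharacterMatrix) -> np.ndarray:
    enc = encode_matrix(m, taxa=t.leaf_labels)
    down, _, _ = _sankoff_costs(t, enc)
    return down[id(t.root)].min(axis=1).astype(np.int32)


# ---------------------------------------------------------------------------
# Hypothetical ancestors
# ---------------------------------------------------------------------------


def export_hypothetical_ancestors(
    ref: PhyloTree,
    m: CharacterMatrix,
    mode: str = "acctran",
    name_prefix: str = "Node",
) -> CharacterMatrix:
    """Synthesize one terminal row per internal node of a reference topology.

    Characters are optimized on ``ref`` (which may contain polytomies) and
    each internal node's states are exported as a new taxon row named
    ``Node<i>`` (preorder numbering, root = 1).  Ambiguous optimizations
    under the chosen mode are exported as the full ambiguity set
    (a polymorphic cell); characters inapplicable across all of a node's
    descendants are exported INAPPLICABLE, and characters unobserved across
    all descendants are exported MISSING.
    """
    if mode not in ("acctran", "deltran"):
        raise ParsimonyError(f"unknown mode {mode!r}")
    absent = set(ref.leaf_labels) - set(m.taxa)
    if absent:
        raise ParsimonyError(f"reference leaves missing from matrix: {sorted(absent)}")
    sub = m.select_taxa(ref.leaf_labels)
    recon = reconstruct_ancestral_states(ref, sub, mode="both")
    sets = recon.acctran_sets if mode == "acctran" else recon.deltran_sets
    node_num = _number_internal(ref)
    tax_idx = {tname: i for i, tname in enumerate(sub.taxa)}

    rows: list[list] = []
    names: list[str] = []
    for node in ref.preorder():
        if node.is_leaf():
            continue
        nid = node_num[id(node)]
        desc = [tax_idx[lab] for lab in _descendant_leaves(node)]
        row: list = []
        for j in range(sub.n_chars):
            cells = [sub.cells[i][j] for i in desc]
            if all(c is INAPPLICABLE for c in cells):
                row.append(INAPPLICABLE)
            elif all(not isinstance(c, frozenset) for c in cells):
                row.append(MISSING)
            else:
                row.append(sets[nid][j])
        names.append(f"{name_prefix}{nid}")
        rows.append(row)
    return CharacterMatrix(names, rows, list(sub.partitions))


def _descendant_leaves(node: TreeNode) -> list[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n.label)
        else:
            stack.extend(n.children)
    return out
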