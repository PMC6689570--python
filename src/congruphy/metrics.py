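"""Congruence metrics between a test tree and a reference tree.

All metrics operate on unrooted topologies with identical leaf sets (prune
first when taxon samples differ):

* quartet status counts — the five-way classification of all C(n,4) leaf
  quartets (same resolution, different resolution, resolved in one tree
  only, unresolved in both);
* quartet divergence — a symmetric-difference measure normalized against the
  maximum resolvable information, (2d + r1 + r2) / 2Q, so a quartet resolved
  in only one tree costs half as much as an outright conflict;
* shared-quartet proportion — s / (s + d + r2), shared resolved quartets over
  the quartets resolved in the *reference*; polytomies in the reference drop
  out of the denominator by construction (not symmetric in its arguments);
* Robinson–Foulds distance, raw and scaled by the test tree's resolution
  fraction (non-trivial splits over the binary maximum n - 3);
* shared partition count (unrooted splits present in both trees), with a
  rooted-clade variant.

The quartet classifier is vectorized over all quartets and split rows; it
agrees exactly with brute-force enumeration (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .trees import PhyloTree, TreeError, rooted_clades, split_blocks


class MetricError(ValueError):
    """Invalid input to a congruence metric."""


@dataclass(frozen=True)
class QuartetStatusCounts:
    """Classification of every leaf quartet for an (unrooted) tree pair."""

    Q: int  # total quartets, C(n, 4)
    s: int  # resolved identically in both trees
    d: int  # resolved differently in both trees
    r1: int  # resolved only in tree 1
    r2: int  # resolved only in tree 2
    u: int  # unresolved in both

    def __post_init__(self) -> None:
        if self.s + self.d + self.r1 + self.r2 + self.u != self.Q:
            raise MetricError("quartet counts do not sum to Q")
        if min(self.Q, self.s, self.d, self.r1, self.r2, self.u) < 0:
            raise MetricError("negative quartet count")


def _check_leafsets(t1: PhyloTree, t2: PhyloTree, minimum: int = 4) -> list[str]:
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        raise MetricError("trees must share an identical leaf set (prune first)")
    if len(l1) < minimum:
        raise MetricError(f"need at least {minimum} shared leaves, have {len(l1)}")
    return l1


def _split_matrix(t: PhyloTree, leaf_order: list[str]) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(leaf_order)}
    blocks = split_blocks(t)
    mat = np.zeros((len(blocks), len(leaf_order)), dtype=bool)
    for r, b in enumerate(blocks):
        for lab in b:
            mat[r, pos[lab]] = True
    return mat


def _quartet_topologies(
    smat: np.ndarray, quartets: np.ndarray
) -> np.ndarray:
    """Topology code per quartet: 0 unresolved, 1 ab|cd, 2 ac|bd, 3 ad|bc.

    ``quartets`` holds sorted leaf indices (a < b < c < d) per row.
    """
    codes = np.zeros(len(quartets), dtype=np.uint8)
    qa, qb, qc, qd = quartets.T
    for row in smat:
        todo = codes == 0
        if not todo.any():
            break
        ma, mb = row[qa[todo]], row[qb[todo]]
        mc, md = row[qc[todo]], row[qd[todo]]
        code = np.zeros(todo.sum(), dtype=np.uint8)
        code[(ma == mb) & (mc == md) & (ma != mc)] = 1
        code[(ma == mc) & (mb == md) & (ma != mb)] = 2
        code[(ma == md) & (mb == mc) & (ma != mb)] = 3
        codes[np.flatnonzero(todo)] = code
    return codes


def quartet_status_counts(t1: PhyloTree, t2: PhyloTree) -> QuartetStatusCounts:
    """Classify every 4-leaf subset by its induced topology in each tree."""
    leaves = _check_leafsets(t1, t2)
    n = len(leaves)
    quartets = np.array(list(combinations(range(n), 4)), dtype=np.int32)
    c1 = _quartet_topologies(_split_matrix(t1, leaves), quartets)
    c2 = _quartet_topologies(_split_matrix(t2, leaves), quartets)
    res1, res2 = c1 > 0, c2 > 0
    s = int(np.sum(res1 & res2 & (c1 == c2)))
    d = int(np.sum(res1 & res2 & (c1 != c2)))
    r1 = int(np.sum(res1 & ~res2))
    r2 = int(np.sum(~res1 & res2))
    u = int(np.sum(~res1 & ~res2))
    return QuartetStatusCounts(len(quartets), s, d, r1, r2, u)


def quartet_divergence(c: QuartetStatusCounts) -> float:
    """(2d + r1 + r2) / 2Q: 0 for identical binary trees, 1 for total conflict."""
    if c.Q == 0:
        raise MetricError("no quartets to compare")
    return (2 * c.d + c.r1 + c.r2) / (2 * c.Q)


def shared_quartet_proportion(c: QuartetStatusCounts) -> float:
    """s / (s + d + r2): shared quartets over quartets resolved in the
    reference (tree 2)."""
    denom = c.s + c.d + c.r2
    if denom == 0:
        raise MetricError("reference tree resolves no quartets")
    return c.s / denom


@dataclass(frozen=True)
class RFResult:
    """Raw and resolution-scaled Robinson–Foulds distance."""

    raw: int
    normalized: float
    test_resolution: float  # non-trivial splits of the test tree over n - 3


def normalized_rf(t1: PhyloTree, t2: PhyloTree) -> RFResult:
    """Symmetric split difference scaled by the test tree's resolution.

    ``t1`` is the test tree; its resolution fraction is its non-trivial split
    count over the binary maximum (n - 3).  A completely unresolved test tree
    has no defined scaled distance and raises.
    """
    leaves = _check_leafsets(t1, t2)
    n = len(leaves)
    s1, s2 = split_blocks(t1), split_blocks(t2)
    raw = len(s1 ^ s2)
    resolution = len(s1) / (n - 3)
    if resolution == 0:
        raise MetricError("test tree is a star: scaled RF undefined")
    return RFResult(raw, raw / resolution, resolution)


def shared_partitions(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial unrooted splits present in both trees."""
    _check_leafsets(t1, t2)
    return len(split_blocks(t1) & split_blocks(t2))


def shared_clades(t1: PhyloTree, t2: PhyloTree) -> int:
    """Rooted variant: matched non-trivial clades given the trees' rootings."""
    _check_leafsets(t1, t2, minimum=3)
    return len(rooted_clades(t1) & rooted_clades(t2))


def compare_trees(test: PhyloTree, ref: PhyloTree) -> dict:
    """All congruence metrics of ``test`` against ``ref`` in one pass.

    Returns a plain dict with the raw quartet counts and every
    normalization, suitable for JSON export.  The scaled RF is ``None``
    when the test tree is a star.
    """
    c = quartet_status_counts(test, ref)
    try:
        rf = normalized_rf(test, ref)
        rf_norm = rf.normalized
        rf_raw = rf.raw
    except MetricError:
        rf_raw = len(split_blocks(test) ^ split_blocks(ref))
        rf_norm = None
    out = {
        "n_leaves": len(test.leaf_labels),
        "quartets": {"Q": c.Q, "s": c.s, "d": c.d, "r1": c.r1, "r2": c.r2, "u": c.u},
        "quartet_divergence": quartet_divergence(c),
        "shared_quartet_proportion": (
            shared_quartet_proportion(c) if (c.s + c.d + c.r2) else None
        ),
        "rf_raw": rf_raw,
        "rf_normalized": rf_norm,
        "shared_partitions": shared_partitions(test, ref),
        "shared_clades": shared_clades(test, ref),
    }
    return out
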