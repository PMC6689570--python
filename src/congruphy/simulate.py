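"""Synthetic datasets with the statistical structure of a total-evidence
morphology+DNA study of extant and fossil taxa.

The generator emulates the study design the analysis pipeline assumes:

* a known, clock-like "true" tree over extant taxa (birth–death shape), from
  which a well-corroborated *reference* tree is obtained by restricting to a
  designated core subset and optionally collapsing a fraction of internal
  edges into polytomies;
* morphological characters (unordered, 2–4 states) evolved down the full
  tree under a symmetric Mk model with discretized-gamma rate heterogeneity;
* a large molecular partition (4-state sites plus binary indel characters)
  present only for extant taxa;
* fossil tips attached to internal edges with short terminal branches, so a
  fossil's root-to-tip path is stochastically much shorter than an extant
  tip's — the temporal-proximity signal that makes fossil morphology
  resemble hypothetical ancestors;
* missing data: a per-cell missing fraction for extant morphology and an
  extra fraction for fossils (emulating incomplete skeletons), plus a small
  inapplicable fraction in morphology.

Default counts mirror the empirical study dimensions (60 extant genera with
a 41-taxon core, 42 fossils, 219 morphological characters, 15,407 DNA sites,
188 indels); experiments and tests pass scaled-down configs explicitly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .characters import (
    DNA,
    INAPPLICABLE,
    INDEL,
    MISSING,
    MORPHOLOGY,
    CharacterMatrix,
    combine_partitions,
    write_nexus,
)
from .trees import PhyloTree, TreeNode, prune, write_tree


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic dataset.

    Rates are expected substitutions per character along a root-to-tip path
    (tree height is normalized to 1).  ``fossil_branch_scale`` scales fossil
    terminal branches relative to the mean extant terminal branch and must be
    < 1 so fossils sit close to the internal nodes they attach beside.
    """

    n_extant: int = 60
    n_core: int = 41  # clamped to n_extant when the extant sample is smaller
    n_fossil: int = 42
    n_morph_chars: int = 219
    n_dna_sites: int = 15_407
    n_indels: int = 188
    morph_state_weights: dict = field(default_factory=lambda: {2: 0.6, 3: 0.25, 4: 0.15})
    morph_rate: float = 1.0
    dna_rate: float = 2.0
    indel_rate: float = 0.3
    gamma_shape: float = 0.5
    gamma_categories: int = 4
    extant_missing_fraction: float = 0.05
    fossil_extra_missing_fraction: float = 0.17
    fossil_block_missing: bool = False  # contiguous blocks (whole regions absent)
    morph_inapplicable_fraction: float = 0.02
    fossil_branch_scale: float = 0.05
    fossil_attach_depth: float = 0.7  # max attachment depth, fraction of tree height
    extant_tip_extension: float = 0.35  # terminal-branch stretch, fraction of height
    noncore_tip_factor: float = 4.0  # extra tip-length multiplier for non-core extant
    convergence_fraction: float = 0.3  # share of morphology prone to convergence
    n_ecomorphs: int = 3  # convergent syndromes taxa can be drawn into
    convergence_rate: float = 0.4  # scales convergent overwrite with tip length squared
    n_molecular_rogues: int = 2  # core taxa with strongly elevated molecular rates
    molecular_rogue_factor: float = 4.0  # DNA tip-length multiplier for those taxa
    birth_rate: float = 1.0
    death_rate: float = 0.5
    collapse_fraction: float = 0.1
    clock: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_extant < 4:
            raise SimulationError("need at least 4 extant taxa")
        if self.n_core <= 0:
            raise SimulationError("core size must be positive")
        for name in (
            "extant_missing_fraction",
            "fossil_extra_missing_fraction",
            "morph_inapplicable_fraction",
            "collapse_fraction",
            "fossil_attach_depth",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.fossil_branch_scale < 1):
            raise SimulationError("fossil_branch_scale must be in (0, 1)")
        if self.extant_tip_extension < 0:
            raise SimulationError("extant_tip_extension must be non-negative")
        if self.noncore_tip_factor < 1:
            raise SimulationError("noncore_tip_factor must be >= 1")
        if not (0 <= self.convergence_fraction <= 1) or self.convergence_rate < 0:
            raise SimulationError("invalid convergence parameters")
        if self.n_ecomorphs < 1:
            raise SimulationError("need at least one ecomorph class")
        if self.n_molecular_rogues < 0 or self.molecular_rogue_factor < 1:
            raise SimulationError("invalid molecular-rogue parameters")
        if min(self.n_fossil, self.n_morph_chars, self.n_dna_sites, self.n_indels) < 0:
            raise SimulationError("counts must be non-negative")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise SimulationError("invalid birth/death rates")


@dataclass
class SyntheticDataset:
    """A complete synthetic study: trees, matrix, and taxon roles."""

    reference_tree: PhyloTree  # true tree restricted to core (maybe polytomous)
    true_tree: PhyloTree  # full tree including fossil tips, with lengths
    matrix: CharacterMatrix  # morphology + dna + indel over all taxa
    roles: dict  # label -> "core" | "other_extant" | "fossil"
    config: SimulationConfig

    @property
    def core_taxa(self) -> list[str]:
        return sorted(k for k, v in self.roles.items() if v == "core")

    @property
    def extant_taxa(self) -> list[str]:
        return sorted(k for k, v in self.roles.items() if v != "fossil")

    @property
    def fossil_taxa(self) -> list[str]:
        return sorted(k for k, v in self.roles.items() if v == "fossil")

    def write(self, directory) -> None:
        """Write NEXUS matrix, Newick trees, and a JSON manifest."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "matrix.nex").write_text(write_nexus(self.matrix))
        (d / "reference.nwk").write_text(write_tree(self.reference_tree) + "\n")
        (d / "true_tree.nwk").write_text(write_tree(self.true_tree) + "\n")
        manifest = {"roles": self.roles, "config": asdict(self.config)}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _normalize_height(t: PhyloTree) -> None:
    def depth(node: TreeNode, acc: float) -> float:
        if node.is_leaf():
            return acc
        return max(depth(c, acc + (c.length or 0.0)) for c in node.children)

    h = depth(t.root, 0.0)
    if h <= 0:
        raise SimulationError("degenerate tree height")
    for node in t.postorder():
        if node.length is not None:
            node.length /= h


def collapse_edges(t: PhyloTree, fraction: float, rng: np.random.Generator) -> PhyloTree:
    """Collapse a random fraction of internal (non-root) edges to polytomies."""
    t = t.copy()
    internal = [n for n in t.preorder() if not n.is_leaf() and n.parent is not None]
    k = int(round(fraction * len(internal)))
    if k == 0:
        return t
    chosen = rng.choice(len(internal), size=k, replace=False)
    for i in chosen:
        node = internal[i]
        p = node.parent
        idx = p.children.index(node)
        p.children[idx : idx + 1] = node.children
        for c in node.children:
            c.parent = p
            c.length = (c.length or 0.0) + (node.length or 0.0)
    return t


def simulate_reference_tree(
    cfg: SimulationConfig, collapse: float | None = None
) -> PhyloTree:
    """Rooted tree over the extant taxa with branch lengths (height 1).

    Birth–death shape; ultrametric in clock mode.  Every extant terminal
    branch is stretched by ``extant_tip_extension`` x tree height before
    renormalization, emulating sparse taxon sampling where each sampled tip
    sits far from its last common ancestors (the long extant root-to-tip
    paths that fossils break up).  ``collapse`` (default:
    ``cfg.collapse_fraction``) randomly collapses that fraction of internal
    edges into polytomies, emulating an incompletely resolved reference.
    """
    cfg.validate()
    pyrng = random.Random(cfg.seed)
    dt = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_extant_tips=cfg.n_extant,
        rng=pyrng,
    )
    labels = [f"E{i + 1:02d}" for i in range(cfg.n_extant)]
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = labels[i]

    def rec(dn) -> TreeNode:
        if dn.is_leaf():
            return TreeNode(dn.taxon.label, dn.edge.length or 0.0)
        node = TreeNode(None, dn.edge.length or 0.0)
        for c in dn.child_nodes():
            node.add_child(rec(c))
        return node

    root = rec(dt.seed_node)
    root.length = None
    t = PhyloTree(root)
    _normalize_height(t)
    if cfg.extant_tip_extension > 0:
        for leaf in t.leaves():
            leaf.length = (leaf.length or 0.0) + cfg.extant_tip_extension
        _normalize_height(t)
    if not cfg.clock:
        rng = np.random.default_rng(cfg.seed + 1)
        for node in t.postorder():
            if node.length is not None:
                node.length *= float(rng.lognormal(0.0, 0.3))
    frac = cfg.collapse_fraction if collapse is None else collapse
    if frac > 0:
        t = collapse_edges(t, frac, np.random.default_rng(cfg.seed + 2))
    return t


def attach_fossil_tips(
    tree: PhyloTree, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> PhyloTree:
    """Attach ``cfg.n_fossil`` short-branch tips at controlled depths.

    For each fossil a target attachment depth is drawn uniformly on
    (0, ``fossil_attach_depth``] (as a fraction of tree height), an edge
    spanning that depth is chosen uniformly, and the fossil is attached there
    with a terminal branch of ``fossil_branch_scale`` times the mean extant
    terminal branch (jittered).  Fossil root-to-tip depths are therefore
    stochastically much shorter than extant depths — the temporal-proximity
    premise that fossil phenotypes resemble common ancestors.
    """
    if not tree.has_branch_lengths():
        raise SimulationError("fossil attachment requires branch lengths")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    t = tree.copy()
    if cfg.n_fossil == 0:
        return t
    term_mean = float(np.mean([n.length or 0.0 for n in t.leaves()]))

    def node_depths() -> dict[int, float]:
        out = {id(t.root): 0.0}
        for node in t.preorder():
            if node.parent is not None:
                out[id(node)] = out[id(node.parent)] + (node.length or 0.0)
        return out

    for i in range(cfg.n_fossil):
        depths = node_depths()
        height = max(depths.values())
        target = float(rng.uniform(0.0, cfg.fossil_attach_depth)) * height
        spanning = [
            n
            for n in t.preorder()
            if n.parent is not None
            and depths[id(n.parent)] <= target <= depths[id(n)]
            and (n.length or 0.0) > 0
        ]
        if not spanning:  # target shallower than the first split: use root edges
            spanning = [c for c in t.root.children if (c.length or 0.0) > 0]
        edge = spanning[int(rng.integers(len(spanning)))]
        pos = min(max(target - depths[id(edge.parent)], 0.0), edge.length or 0.0)
        p = edge.parent
        u = TreeNode(None, pos)
        p.children[p.children.index(edge)] = u
        u.parent = p
        u.add_child(edge)
        edge.length = (edge.length or 0.0) - pos
        fossil = TreeNode(
            f"F{i + 1:02d}",
            cfg.fossil_branch_scale * term_mean * float(rng.uniform(0.5, 1.5)),
        )
        u.add_child(fossil)
    return t


# ---------------------------------------------------------------------------
# Character evolution (symmetric Mk)
# ---------------------------------------------------------------------------


def _discrete_gamma_rates(
    shape: float, categories: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-character rate multipliers from a discretized gamma (mean 1)."""
    from scipy import stats

    if shape <= 0:
        raise SimulationError("gamma shape must be positive")
    qs = (np.arange(categories) + 0.5) / categories
    cats = stats.gamma.ppf(qs, a=shape, scale=1.0 / shape)
    cats = cats / cats.mean()
    return cats[rng.integers(categories, size=n)]


def evolve_characters(
    tree: PhyloTree,
    n_chars: int,
    n_states,
    rate: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    tag: str = MORPHOLOGY,
    symbols: Sequence[str] | None = None,
) -> CharacterMatrix:
    """Evolve unordered characters down the tree under a symmetric Mk model.

    ``n_states`` is an int or a per-character array.  Under the k-state
    symmetric model the probability that the state at the end of a branch of
    length t (at rate r) differs from the start is
    (k-1)/k * (1 - exp(-k/(k-1) * r * t)); a changed state is uniform over
    the k-1 alternatives.  Gamma rate heterogeneity is applied per character.
    """
    if not tree.has_branch_lengths() and rate > 0:
        import warnings

        warnings.warn("tree has no branch lengths; characters will be constant")
    k = np.broadcast_to(np.asarray(n_states, dtype=np.int64), (n_chars,)).copy()
    if (k < 2).any():
        raise SimulationError("characters need at least 2 states")
    rates = rate * _discrete_gamma_rates(
        cfg.gamma_shape, cfg.gamma_categories, n_chars, rng
    )
    states: dict[int, np.ndarray] = {}
    order = list(tree.preorder())
    states[id(order[0])] = (rng.random(n_chars) * k).astype(np.int64)
    for node in order[1:]:
        parent_states = states[id(node.parent)]
        tlen = node.length or 0.0
        kk = k.astype(float)
        p_change = (kk - 1) / kk * (1 - np.exp(-kk / (kk - 1) * rates * tlen))
        change = rng.random(n_chars) < p_change
        offset = rng.integers(1, k)  # uniform over the k-1 other states
        new = np.where(change, (parent_states + offset) % k, parent_states)
        states[id(node)] = new
    if symbols is None:
        symbols = [str(i) for i in range(int(k.max()))]
    rows = []
    taxa = []
    for leaf in tree.leaves():
        st = states[id(leaf)]
        rows.append([frozenset((symbols[int(s)],)) for s in st])
        taxa.append(leaf.label)
    return CharacterMatrix(taxa, rows, [tag] * n_chars)


def _apply_convergence(
    m: CharacterMatrix,
    tree: PhyloTree,
    char_states: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Overwrite states of convergence-prone characters along long tips.

    Each taxon is assigned one of ``n_ecomorphs`` convergent syndromes; for a
    random ``convergence_fraction`` of characters each syndrome has a target
    state, and a taxon's cell is pulled to its syndrome's target with
    probability 1 - exp(-convergence_rate x terminal branch length squared).
    Adaptive convergence accelerates with time spent on a terminal branch, so
    long-tipped extant lineages are strongly affected while short-branched
    fossils and densely sampled core taxa largely escape it — morphology's
    classic failure mode.
    """
    if cfg.convergence_fraction == 0 or cfg.convergence_rate == 0:
        return
    n_conv = int(round(cfg.convergence_fraction * m.n_chars))
    if n_conv == 0:
        return
    conv_cols = np.sort(rng.choice(m.n_chars, size=n_conv, replace=False))
    targets = np.stack(
        [(rng.random(n_conv) * char_states[conv_cols]).astype(np.int64)
         for _ in range(cfg.n_ecomorphs)]
    )
    term = {leaf.label: (leaf.length or 0.0) for leaf in tree.leaves()}
    eco = {t: int(rng.integers(cfg.n_ecomorphs)) for t in m.taxa}
    for i, taxon in enumerate(m.taxa):
        p = 1.0 - np.exp(-cfg.convergence_rate * term.get(taxon, 0.0) ** 2)
        pulled = rng.random(n_conv) < p
        for jj in np.nonzero(pulled)[0]:
            col = int(conv_cols[jj])
            m.cells[i][col] = frozenset((str(targets[eco[taxon], jj]),))


def _apply_missing(
    m: CharacterMatrix,
    taxon_fractions: dict[str, float],
    rng: np.random.Generator,
    sentinel=MISSING,
    inapplicable_fraction: float = 0.0,
) -> None:
    """In-place missing-at-random masking, plus optional inapplicable cells."""
    for i, t in enumerate(m.taxa):
        f = taxon_fractions.get(t, 0.0)
        u = rng.random(m.n_chars)
        for j in range(m.n_chars):
            if u[j] < f:
                m.cells[i][j] = sentinel
            elif inapplicable_fraction and u[j] > 1 - inapplicable_fraction:
                m.cells[i][j] = INAPPLICABLE


def build_synthetic_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """End-to-end synthetic study: trees, combined matrix, taxon roles.

    Morphology is present for all taxa (fossils with extra missingness); DNA
    and indel characters are entirely MISSING for fossils.  The reference
    tree is the true tree restricted to a random core subset of extant taxa,
    with a fraction of its internal edges collapsed.  Extant taxa outside the
    core get an extra terminal-branch multiplier (``noncore_tip_factor``):
    the lineages a well-corroborated reference omits are in practice the
    unstable, long-branched ones.  Byte-identical outputs for identical
    configs.
    """
    cfg.validate()
    extant_tree = simulate_reference_tree(cfg, collapse=0.0)
    rng = np.random.default_rng(cfg.seed + 10)

    extant = [n.label for n in extant_tree.leaves()]
    n_core = min(cfg.n_core, cfg.n_extant)
    core = sorted(rng.choice(sorted(extant), size=n_core, replace=False).tolist())
    full_tree = attach_fossil_tips(extant_tree, cfg, rng)
    fossils = [lab for lab in full_tree.leaf_labels if lab.startswith("F")]
    if cfg.noncore_tip_factor > 1:
        for leaf in full_tree.leaves():
            if leaf.label in extant and leaf.label not in core:
                leaf.length = (leaf.length or 0.0) * cfg.noncore_tip_factor
    roles = {lab: ("core" if lab in core else "other_extant") for lab in extant}
    roles.update({lab: "fossil" for lab in fossils})

    # morphology state counts
    ks = sorted(cfg.morph_state_weights)
    ws = np.array([cfg.morph_state_weights[k] for k in ks], dtype=float)
    ws = ws / ws.sum()
    morph_k = np.array(ks)[rng.choice(len(ks), size=cfg.n_morph_chars, p=ws)]

    morph = evolve_characters(
        full_tree, cfg.n_morph_chars, morph_k, cfg.morph_rate, cfg, rng, MORPHOLOGY
    )
    _apply_convergence(morph, full_tree, morph_k, cfg, rng)
    parts = [morph]
    extant_only = prune(full_tree, extant) if fossils else full_tree
    # Molecular rate variation: a few core lineages evolve DNA much faster,
    # so parsimony on molecular data alone commits a persistent long-branch
    # error that morphology can correct (the classic mixed-signal situation).
    n_rogue = min(cfg.n_molecular_rogues, len(core))
    if n_rogue and cfg.molecular_rogue_factor > 1:
        mol_rogues = set(rng.choice(core, size=n_rogue, replace=False).tolist())
        extant_only = extant_only.copy()
        for leaf in extant_only.leaves():
            if leaf.label in mol_rogues:
                leaf.length = (leaf.length or 0.0) * cfg.molecular_rogue_factor
    if cfg.n_dna_sites:
        parts.append(
            evolve_characters(
                extant_only, cfg.n_dna_sites, 4, cfg.dna_rate, cfg, rng, DNA,
                symbols="ACGT",
            )
        )
    if cfg.n_indels:
        parts.append(
            evolve_characters(
                extant_only, cfg.n_indels, 2, cfg.indel_rate, cfg, rng, INDEL
            )
        )

    fractions = {lab: cfg.extant_missing_fraction for lab in extant}
    if not cfg.fossil_block_missing:
        fractions.update(
            {
                lab: cfg.extant_missing_fraction + cfg.fossil_extra_missing_fraction
                for lab in fossils
            }
        )
    _apply_missing(
        morph,
        fractions,
        rng,
        inapplicable_fraction=cfg.morph_inapplicable_fraction,
    )
    if cfg.fossil_block_missing and cfg.fossil_extra_missing_fraction > 0:
        # whole anatomical regions absent: one contiguous window per fossil
        width = int(round(cfg.fossil_extra_missing_fraction * morph.n_chars))
        for lab in fossils:
            i = morph.taxon_index(lab)
            start = int(rng.integers(0, max(morph.n_chars - width, 0) + 1))
            for j in range(start, start + width):
                morph.cells[i][j] = MISSING

    matrix = combine_partitions(parts)  # fossils auto-filled MISSING in dna/indel

    reference = prune(extant_tree, core)
    if cfg.collapse_fraction > 0:
        reference = collapse_edges(
            reference, cfg.collapse_fraction, np.random.default_rng(cfg.seed + 2)
        )
    return SyntheticDataset(reference, full_tree, matrix, roles, cfg)
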