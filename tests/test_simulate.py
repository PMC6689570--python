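"""Synthetic-data generator: trees, Mk evolution, fossils, missingness."""

import numpy as np
import pytest

from congruphy.characters import DNA, MISSING, MORPHOLOGY, write_nexus
from congruphy.simulate import (
    SimulationConfig,
    SimulationError,
    attach_fossil_tips,
    build_synthetic_dataset,
    collapse_edges,
    evolve_characters,
    simulate_reference_tree,
)
from congruphy.trees import prune, split_blocks, write_tree


def leaf_depths(tree):
    out = {}

    def rec(node, acc):
        if node.is_leaf():
            out[node.label] = acc
        for c in node.children:
            rec(c, acc + (c.length or 0.0))

    rec(tree.root, 0.0)
    return out


class TestReferenceTree:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_extant=15, seed=4)
        a = simulate_reference_tree(cfg)
        b = simulate_reference_tree(cfg)
        assert write_tree(a) == write_tree(b)

    def test_collapse_bounds_internal_edges(self):
        cfg = SimulationConfig(n_extant=41, seed=4)
        t = simulate_reference_tree(cfg, collapse=0.1)
        internal_edges = sum(
            1 for n in t.preorder() if not n.is_leaf() and n.parent is not None
        )
        assert internal_edges <= 38  # 41-leaf binary rooted tree has 39

    def test_clock_mode_is_ultrametric_with_unit_height(self):
        cfg = SimulationConfig(n_extant=12, seed=4, extant_tip_extension=0.0)
        t = simulate_reference_tree(cfg, collapse=0.0)
        depths = leaf_depths(t)
        assert max(depths.values()) == pytest.approx(1.0)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            simulate_reference_tree(SimulationConfig(n_extant=3))
        with pytest.raises(SimulationError):
            simulate_reference_tree(SimulationConfig(fossil_branch_scale=1.5))


class TestEvolveCharacters:
    def _tree(self, cfg):
        return simulate_reference_tree(cfg, collapse=0.0)

    def test_rate_zero_gives_constant_characters(self):
        cfg = SimulationConfig(n_extant=8, seed=1)
        m = evolve_characters(self._tree(cfg), 20, 2, 0.0, cfg, np.random.default_rng(1))
        for j in range(m.n_chars):
            assert len({next(iter(row[j])) for row in m.cells}) == 1

    def test_saturation_approaches_mk_limit(self):
        """Sister tips at tiny distance barely differ; distant tips on binary
        characters differ in about half the sites (checked within 3 SD)."""
        from congruphy.trees import PhyloTree, TreeNode

        root = TreeNode()
        a = TreeNode("near1", 0.005)
        b = TreeNode("near2", 0.005)
        u = TreeNode(None, 3.0)
        u.add_child(TreeNode("far1", 3.0))
        u.add_child(TreeNode("far2", 3.0))
        v = TreeNode(None, 0.005)
        v.add_child(a)
        v.add_child(b)
        root.add_child(u)
        root.add_child(v)
        tree = PhyloTree(root)
        cfg = SimulationConfig(gamma_shape=100.0)  # near-homogeneous rates
        n = 4000
        m = evolve_characters(tree, n, 2, 1.0, cfg, np.random.default_rng(3))
        idx = {t: i for i, t in enumerate(m.taxa)}
        near_diff = sum(
            m.cells[idx["near1"]][j] != m.cells[idx["near2"]][j] for j in range(n)
        ) / n
        far_diff = sum(
            m.cells[idx["far1"]][j] != m.cells[idx["far2"]][j] for j in range(n)
        ) / n
        assert near_diff < 0.03
        assert abs(far_diff - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_many_sites_let_mp_recover_the_true_tree(self):
        from congruphy.parsimony import mp_search

        cfg = SimulationConfig(n_extant=8, seed=11, extant_tip_extension=0.0)
        tree = self._tree(cfg)
        m = evolve_characters(tree, 3000, 4, 0.5, cfg, np.random.default_rng(11),
                              tag=DNA, symbols="ACGT")
        res = mp_search(m, method="exhaustive", seed=0)
        assert split_blocks(res.trees[0]) == split_blocks(tree)


class TestFossilTips:
    def test_zero_fossils_is_identity(self):
        cfg = SimulationConfig(n_extant=10, n_fossil=0, seed=2)
        t = simulate_reference_tree(cfg, collapse=0.0)
        assert write_tree(attach_fossil_tips(t, cfg)) == write_tree(t)

    def test_fossils_added_with_short_terminal_branches(self):
        cfg = SimulationConfig(n_extant=12, n_fossil=8, seed=2, fossil_branch_scale=0.1)
        t = simulate_reference_tree(cfg, collapse=0.0)
        full = attach_fossil_tips(t, cfg)
        fossils = [n for n in full.leaves() if n.label.startswith("F")]
        assert len(fossils) == 8
        extant_term = np.mean([n.length for n in t.leaves()])
        for f in fossils:
            assert f.length < 0.1 * extant_term * 1.5 + 1e-12

    def test_mean_fossil_depth_below_extant_depth(self):
        cfg = SimulationConfig(n_extant=15, n_fossil=10, seed=6)
        t = simulate_reference_tree(cfg, collapse=0.0)
        d = leaf_depths(attach_fossil_tips(t, cfg))
        fossil = np.mean([v for k, v in d.items() if k.startswith("F")])
        extant = np.mean([v for k, v in d.items() if k.startswith("E")])
        assert fossil < extant

    def test_removing_fossils_recovers_original_splits(self):
        cfg = SimulationConfig(n_extant=12, n_fossil=6, seed=3)
        t = simulate_reference_tree(cfg, collapse=0.0)
        full = attach_fossil_tips(t, cfg)
        extant = [n.label for n in t.leaves()]
        assert split_blocks(prune(full, extant)) == split_blocks(t)

    def test_lengthless_tree_rejected(self):
        from congruphy.trees import parse_tree

        cfg = SimulationConfig(n_fossil=1)
        with pytest.raises(SimulationError):
            attach_fossil_tips(parse_tree("((A,B),(C,D));"), cfg)


class TestBuildDataset:
    CFG = SimulationConfig(
        n_extant=12, n_core=9, n_fossil=4, n_morph_chars=60,
        n_dna_sites=100, n_indels=10, seed=13,
    )

    def test_taxon_roles_and_counts(self):
        ds = build_synthetic_dataset(self.CFG)
        assert ds.matrix.n_taxa == 16
        assert len(ds.core_taxa) == 9
        assert len(ds.fossil_taxa) == 4
        assert set(ds.roles.values()) == {"core", "other_extant", "fossil"}
        assert sorted(ds.reference_tree.leaf_labels) == ds.core_taxa

    def test_fossil_molecular_cells_all_missing(self):
        ds = build_synthetic_dataset(self.CFG)
        mol_cols = ds.matrix.columns_with_tags((DNA, "indel"))
        for f in ds.fossil_taxa:
            i = ds.matrix.taxon_index(f)
            assert all(ds.matrix.cells[i][j] is MISSING for j in mol_cols)

    def test_fossil_morphology_extra_missingness_within_3sd(self):
        cfg = SimulationConfig(
            n_extant=12, n_core=9, n_fossil=10, n_morph_chars=400,
            n_dna_sites=0, n_indels=0, seed=13,
            extant_missing_fraction=0.0, fossil_extra_missing_fraction=0.17,
            morph_inapplicable_fraction=0.0,
        )
        ds = build_synthetic_dataset(cfg)
        morph_cols = ds.matrix.columns_with_tags(MORPHOLOGY)
        n_cells = len(ds.fossil_taxa) * len(morph_cols)
        n_missing = sum(
            ds.matrix.cells[ds.matrix.taxon_index(f)][j] is MISSING
            for f in ds.fossil_taxa
            for j in morph_cols
        )
        p = 0.17
        sd = np.sqrt(p * (1 - p) / n_cells)
        assert abs(n_missing / n_cells - p) < 3 * sd

    def test_same_seed_byte_identical_outputs(self):
        a = build_synthetic_dataset(self.CFG)
        b = build_synthetic_dataset(self.CFG)
        assert write_nexus(a.matrix) == write_nexus(b.matrix)
        assert write_tree(a.true_tree) == write_tree(b.true_tree)
        assert write_tree(a.reference_tree) == write_tree(b.reference_tree)

    def test_write_produces_readable_artifacts(self, tmp_path):
        import json

        from congruphy.characters import read_matrix
        from congruphy.trees import parse_tree

        ds = build_synthetic_dataset(self.CFG)
        ds.write(tmp_path)
        m = read_matrix((tmp_path / "matrix.nex").read_text())
        assert m.n_taxa == ds.matrix.n_taxa
        ref = parse_tree((tmp_path / "reference.nwk").read_text())
        assert ref.leaf_labels == ds.reference_tree.leaf_labels
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["roles"] == ds.roles

    def test_block_missing_gives_contiguous_fossil_gaps(self):
        cfg = SimulationConfig(
            n_extant=10, n_core=8, n_fossil=3, n_morph_chars=100,
            n_dna_sites=0, n_indels=0, seed=5,
            extant_missing_fraction=0.0, fossil_extra_missing_fraction=0.2,
            fossil_block_missing=True, morph_inapplicable_fraction=0.0,
        )
        ds = build_synthetic_dataset(cfg)
        for f in ds.fossil_taxa:
            row = ds.matrix.cells[ds.matrix.taxon_index(f)]
            missing = [j for j, c in enumerate(row) if c is MISSING]
            assert len(missing) == 20
            assert missing == list(range(missing[0], missing[0] + 20))

    def test_collapse_edges_only_removes_splits(self):
        cfg = SimulationConfig(n_extant=14, seed=9)
        t = simulate_reference_tree(cfg, collapse=0.0)
        collapsed = collapse_edges(t, 0.3, np.random.default_rng(0))
        assert split_blocks(collapsed) <= split_blocks(t)
        assert len(split_blocks(collapsed)) < len(split_blocks(t))
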