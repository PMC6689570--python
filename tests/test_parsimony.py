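"""Fitch scoring, implied weights, MP search, and ancestral states."""

import random
from itertools import combinations

import numpy as np
import pytest

from congruphy.characters import MISSING, MORPHOLOGY, CharacterMatrix
from congruphy.parsimony import (
    ParsimonyError,
    export_hypothetical_ancestors,
    fitch_length,
    implied_weights_score,
    mp_search,
    reconstruct_ancestral_states,
)
from congruphy.reference import fitch_length_bruteforce, random_binary_tree
from congruphy.trees import (
    PhyloTree,
    TreeNode,
    parse_tree,
    root_on_outgroup,
    split_blocks,
    write_tree,
)
from conftest import toy_matrix


class TestFitchLength:
    def test_clean_split_costs_one_step(self):
        t = parse_tree("((A,B),(C,D));")
        assert fitch_length(t, toy_matrix("ABCD", ["0011"]))[1] == 1

    def test_conflicting_character_costs_two(self):
        t = parse_tree("((A,B),(C,D));")
        assert fitch_length(t, toy_matrix("ABCD", ["0101"]))[1] == 2

    def test_constant_and_missing(self):
        t = parse_tree("((A,B),(C,D));")
        per_char, total = fitch_length(t, toy_matrix("ABCD", ["0000", "0?11"]))
        assert list(per_char) == [0, 1]  # missing taxon scores as if absent

    def test_leaf_without_row_raises(self):
        t = parse_tree("((A,B),(C,E));")
        with pytest.raises(ParsimonyError):
            fitch_length(t, toy_matrix("ABCD", ["0011"]))

    def test_matches_exhaustive_oracle_on_small_instances(self, rng):
        """Bitmask Fitch equals minimization over all internal labelings."""
        for _ in range(60):
            n = rng.randint(4, 7)
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            col = "".join(rng.choice("012?-") for _ in range(n))
            if len({c for c in col if c not in "?-"}) == 0:
                col = "01" + col[2:]
            m = toy_matrix(labels, [col])
            fast = int(fitch_length(tree, m)[0][0])
            assert fast == fitch_length_bruteforce(tree, m, 0), (write_tree(tree), col)

    def test_invariant_under_rerooting_and_row_order(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(labels, rng)
        cols = ["01200121", "000?1122", "01-01-01"]
        m = toy_matrix(labels, cols)
        base = fitch_length(tree, m)[1]
        for out in ("t3", "t7"):
            assert fitch_length(root_on_outgroup(tree, out), m)[1] == base
        shuffled = list(reversed(labels))
        m2 = toy_matrix(shuffled, ["".join(c[labels.index(l)] for l in shuffled) for c in cols])
        assert fitch_length(tree, m2)[1] == base


class TestImpliedWeights:
    def test_homoplasy_free_matrix_scores_zero(self):
        t = parse_tree("((A,B),(C,D));")
        assert implied_weights_score(t, toy_matrix("ABCD", ["0011", "0001"]), 3) == 0.0

    def test_single_extra_step_formula(self):
        t = parse_tree("((A,B),(C,D));")
        # 0101 needs 2 steps, minimum 1 -> e=1 -> 1/(1+3)
        assert implied_weights_score(t, toy_matrix("ABCD", ["0101"]), 3) == pytest.approx(0.25)

    def test_nonpositive_k_rejected(self):
        t = parse_tree("((A,B),(C,D));")
        with pytest.raises(ParsimonyError):
            implied_weights_score(t, toy_matrix("ABCD", ["0011"]), 0)

    def test_monotone_nonincreasing_in_k(self, rng):
        labels = [f"t{i}" for i in range(6)]
        tree = random_binary_tree(labels, rng)
        m = toy_matrix(labels, ["010101", "001122", "011001", "012012"])
        scores = [implied_weights_score(tree, m, k) for k in (1, 2, 4, 8, 32)]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_ranking_matches_bruteforce_on_all_five_taxon_trees(self, rng):
        """Implied-weights ordering over all 15 unrooted 5-taxon topologies."""
        from congruphy.parsimony import _enumerate_unrooted

        labels = list("ABCDE")
        m = toy_matrix(labels, ["00111", "01011", "00122", "01100", "11010"])
        k = 4.0
        scored = []
        for t in _enumerate_unrooted(labels):
            # brute-force score: per-column exhaustive Fitch + the e/(e+k) map
            es = []
            for j in range(m.n_chars):
                steps = fitch_length_bruteforce(t, m, j)
                singles = {next(iter(m.cells[i][j])) for i in range(5)}
                es.append(max(steps - (len(singles) - 1), 0))
            brute = sum(e / (e + k) for e in es)
            fast = implied_weights_score(t, m, k)
            scored.append((brute, fast))
        assert len(scored) == 15
        for brute, fast in scored:
            assert fast == pytest.approx(brute)


class TestMPSearch:
    def test_three_supporting_characters_recover_split(self):
        m = toy_matrix("ABCD", ["0011", "0011", "0011"])
        res = mp_search(m, seed=1)
        assert res.score == 3
        assert split_blocks(res.trees[0]) == {frozenset("CD")}

    def test_exhaustive_equals_heuristic_on_clean_six_taxon_data(self, rng):
        from congruphy.simulate import SimulationConfig, evolve_characters

        labels = [f"t{i}" for i in range(6)]
        true = random_binary_tree(labels, rng, lengths=True)
        cfg = SimulationConfig(seed=5)
        m = evolve_characters(true, 80, 2, 0.3, cfg, np.random.default_rng(5))
        exact = mp_search(m, method="exhaustive", seed=0)
        heur = mp_search(m, method="heuristic", replicates=5, seed=1)
        assert exact.score == pytest.approx(heur.score)
        assert split_blocks(exact.trees[0]) == split_blocks(true)

    def test_optimum_score_deterministic_across_seeds_in_exhaustive_mode(self):
        m = toy_matrix("ABCDE", ["00111", "01011", "00122"])
        s1 = mp_search(m, method="exhaustive", seed=1).score
        s2 = mp_search(m, method="exhaustive", seed=99).score
        assert s1 == s2

    def test_heuristic_never_beats_exhaustive_and_never_loses_to_random(self, rng):
        labels = [f"t{i}" for i in range(7)]
        cols = ["".join(rng.choice("012") for _ in labels) for _ in range(10)]
        m = toy_matrix(labels, cols)
        exact = mp_search(m, method="exhaustive", seed=0)
        heur = mp_search(m, method="heuristic", replicates=4, seed=3)
        assert heur.score >= exact.score - 1e-9
        random_tree = random_binary_tree(labels, rng)
        assert heur.score <= fitch_length(random_tree, m)[1] + 1e-9

    def test_fewer_than_four_taxa_rejected(self):
        with pytest.raises(ParsimonyError):
            mp_search(toy_matrix("ABC", ["011"]), seed=0)

    def test_same_seed_same_result(self):
        m = toy_matrix("ABCDEFGH", ["00110011", "01010101", "00011122", "01200012"])
        r1 = mp_search(m, method="heuristic", replicates=3, seed=7)
        r2 = mp_search(m, method="heuristic", replicates=3, seed=7)
        assert [write_tree(t) for t in r1.trees] == [write_tree(t) for t in r2.trees]

    def test_result_serializes_to_nexus_and_json_metadata(self):
        import json

        from congruphy.trees import read_trees

        m = toy_matrix("ABCDE", ["00011", "00101", "01001"])
        res = mp_search(m, method="exhaustive", seed=0)
        trees = read_trees(res.to_nexus())
        assert len(trees) == len(res.trees) + 1  # optima + strict consensus
        meta = json.loads(json.dumps(res.metadata()))
        assert meta["score"] == res.score and meta["method"] == "exhaustive"

    def test_consensus_is_strict_consensus_of_optima(self):
        # two conflicting characters -> multiple co-optimal trees
        m = toy_matrix("ABCDE", ["00011", "00101", "01001"])
        res = mp_search(m, method="exhaustive", seed=0)
        if len(res.trees) > 1:
            from congruphy.trees import strict_consensus

            assert split_blocks(res.consensus) == split_blocks(strict_consensus(res.trees))


class TestAncestralStates:
    def test_unique_mpr_both_modes_agree(self):
        t = parse_tree("((A,B),(C,D));")
        rec = reconstruct_ancestral_states(t, toy_matrix("ABCD", ["0011"]))
        # node 1 = root, preorder numbering; the AB and CD clades get 0 and 1
        states = {nid: rec.acctran_states[nid][0] for nid in rec.node_ids}
        assert states[2] == "0" and states[3] == "1"
        assert rec.acctran_states == rec.deltran_states

    def test_constant_character_everywhere(self):
        t = parse_tree("((A,B),(C,(D,E)));")
        rec = reconstruct_ancestral_states(t, toy_matrix("ABCDE", ["11111"]))
        for nid in rec.node_ids:
            assert rec.acctran_states[nid] == ["1"]
            assert rec.deltran_states[nid] == ["1"]

    def test_degenerate_root_rejected(self):
        root = TreeNode()
        root.add_child(TreeNode("A"))
        with pytest.raises(ParsimonyError):
            reconstruct_ancestral_states(PhyloTree(root), toy_matrix("A", ["0"]))

    def test_implied_changes_equal_fitch_length_exhaustively(self, rng):
        """Both modes realize the minimum change count (binary chars, <=6 leaves)."""
        for _ in range(40):
            n = rng.randint(4, 6)
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            col = "".join(rng.choice("01") for _ in range(n))
            if len(set(col)) == 1:
                col = "01" + col[2:]
            m = toy_matrix(labels, [col])
            rec = reconstruct_ancestral_states(tree, m)
            expected = int(fitch_length(tree, m)[1])
            assert rec.total_steps == expected
            assert rec.implied_changes(tree, "acctran") == expected
            assert rec.implied_changes(tree, "deltran") == expected

    def test_acctran_prefers_early_deltran_late(self):
        # A=1, rest 0 on a caterpillar: the 1 can be gained on A's branch only
        # (unique MPR), but with two 1-leaves in one clade the modes differ.
        t = parse_tree("(((A,B),C),(D,E));")
        m = toy_matrix("ABCDE", ["11100"])
        rec = reconstruct_ancestral_states(t, m)
        # root tie (0 vs 1): lexicographic root pick is '0'; acctran then pushes
        # the gain of '1' as close to the root as an MPR allows.
        root_id = rec.node_ids[0]
        assert rec.acctran_states[root_id] == ["0"]
        acc_ones = sum(rec.acctran_states[n] == ["1"] for n in rec.node_ids)
        del_ones = sum(rec.deltran_states[n] == ["1"] for n in rec.node_ids)
        assert acc_ones >= del_ones


class TestHypotheticalAncestors:
    def test_one_row_per_internal_node(self):
        t = parse_tree("((A,B),(C,(D,E)));")
        anc = export_hypothetical_ancestors(t, toy_matrix("ABCDE", ["00110", "01100"]))
        assert len(anc.taxa) == 4  # root + 3 internal nodes
        assert anc.taxa[0] == "Node1"

    def test_constant_character_exports_that_state(self):
        t = parse_tree("((A,B),(C,D));")
        anc = export_hypothetical_ancestors(t, toy_matrix("ABCD", ["1111"]))
        assert all(row[0] == frozenset("1") for row in anc.cells)

    def test_all_inapplicable_clade_exports_inapplicable(self):
        from congruphy.characters import INAPPLICABLE

        t = parse_tree("((A,B),(C,D));")
        anc = export_hypothetical_ancestors(t, toy_matrix("ABCD", ["--01"]))
        by_name = dict(zip(anc.taxa, anc.cells))
        assert by_name["Node2"][0] is INAPPLICABLE  # the (A,B) clade

    def test_modes_differ_only_at_ambiguous_characters(self, rng):
        """acctran vs deltran rows may differ only where the MPR set is not
        a singleton."""
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            tree = random_binary_tree(labels, rng)
            cols = ["".join(rng.choice("01") for _ in labels) for _ in range(12)]
            m = toy_matrix(labels, cols)
            acc = export_hypothetical_ancestors(tree, m, "acctran")
            del_ = export_hypothetical_ancestors(tree, m, "deltran")
            rec = reconstruct_ancestral_states(tree, m)
            for r, nid in enumerate(rec.node_ids):
                for j in range(m.n_chars):
                    if acc.cells[r][j] != del_.cells[r][j]:
                        assert len(rec.mpr[nid][j]) > 1

    def test_reincluding_ancestors_on_reference_adds_zero_steps(self, rng):
        """Attaching each exported ancestor beside its node leaves the score
        unchanged (they are most-parsimonious interpolations)."""
        labels = [f"t{i}" for i in range(6)]
        tree = random_binary_tree(labels, rng)
        cols = ["".join(rng.choice("012") for _ in labels) for _ in range(8)]
        m = toy_matrix(labels, cols)
        for mode in ("acctran", "deltran"):
            anc = export_hypothetical_ancestors(tree, m, mode)
            base = fitch_length(tree, m)[1]
            aug = tree.copy()
            i = 0
            for node in aug.preorder():
                if node.is_leaf():
                    continue
                i += 1
                node.add_child(TreeNode(f"Node{i}"))
            big = m.add_rows(anc)
            assert fitch_length(aug, big)[1] == base

    def test_missing_reference_leaf_raises(self):
        t = parse_tree("((A,B),(C,Z));")
        with pytest.raises(ParsimonyError):
            export_hypothetical_ancestors(t, toy_matrix("ABCD", ["0011"]))
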