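"""Scoring correctness against brute-force oracles, Fitch/Sankoff agreement,
per-character step bounds, and CI/RI conventions."""

import numpy as np
import pytest

from parsimonia.matrix import (CharacterMeta, CharacterMatrix, MISSING,
                               StateSet)
from parsimonia.parsimony import (ScoringError, char_max_steps,
                                  char_min_steps, ensemble_indices,
                                  fitch_steps_adj, ordered_length,
                                  sankoff_steps_adj, score_tree, tree_length)
from parsimonia.trees import Tree

from conftest import (exhaustive_topologies, matrix_from_strings,
                      oracle_unrooted_length, random_matrix)


def _tree(newick: str) -> Tree:
    return Tree.from_newick(newick)


class TestTreeLength:
    def test_constant_character_is_free(self):
        m = matrix_from_strings({"A": "0", "B": "0", "C": "0", "D": "0"})
        assert tree_length(_tree("((A,B),(C,D));"), m).length == 0

    def test_four_taxon_split(self):
        m = matrix_from_strings({"A": "0", "B": "0", "C": "1", "D": "1"})
        assert tree_length(_tree("((A,B),(C,D));"), m).length == 1
        assert tree_length(_tree("((A,C),(B,D));"), m).length == 2

    def test_missing_never_forces_a_step(self):
        m = matrix_from_strings({"A": "0", "B": "?", "C": "1", "D": "1"})
        assert tree_length(_tree("((A,B),(C,D));"), m).length == 1

    def test_polymorphic_tip_contributes_its_set(self):
        m = matrix_from_strings({"A": "{01}", "B": "0", "C": "1", "D": "1"})
        assert tree_length(_tree("((A,B),(C,D));"), m).length == 1

    def test_leaf_mismatch_is_error(self):
        m = matrix_from_strings({"A": "0", "B": "1", "C": "1"})
        with pytest.raises(ScoringError):
            tree_length(_tree("((A,B),(C,X));"), m)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Fitch equals minimisation over every internal assignment."""
        for _ in range(20):
            m = random_matrix(rng, 5, 4, n_states=3)
            cols = [[m.cells[i][j].states if not m.cells[i][j].is_uncertain
                     else frozenset(range(3)) for i in range(5)]
                    for j in range(4)]
            topo = ((0, 1), (2, 3), 4)
            nwk = "((t0,t1),(t2,t3),t4);"
            expected = sum(oracle_unrooted_length(col, topo, 3) for col in cols)
            assert tree_length(_tree(nwk), m).length == expected

    def test_invariant_under_rerooting_and_rotation(self, rng):
        m = random_matrix(rng, 6, 8, n_states=3)
        forms = [
            "((t0,t1),(t2,t3),(t4,t5));",
            "((t2,t3),(t0,t1),(t5,t4));",
            "(t0,t1,((t2,t3),(t4,t5)));",
            "((((t2,t3),(t4,t5)),t1),t0);",  # rooted on t0's edge
        ]
        lengths = {tree_length(_tree(f), m).length for f in forms}
        assert len(lengths) == 1

    def test_missing_only_character_changes_nothing(self, rng):
        m = random_matrix(rng, 5, 6, n_states=2, p_missing=0)
        cells = [row + [MISSING] for row in m.cells]
        m2 = CharacterMatrix(m.taxa, cells)
        t = _tree("((t0,t1),(t2,t3),t4);")
        assert tree_length(t, m2).length == tree_length(t, m).length
        assert score_tree(t, m2).max_sum == score_tree(t, m).max_sum


class TestOrderedScoring:
    def test_two_taxon_cost_definition(self):
        m = matrix_from_strings({"A": "0", "B": "2", "C": "0"})
        assert tree_length(_tree("(A,B,C);"), m).length == 1
        m.set_ordered([1])
        assert ordered_length(_tree("(A,B,C);"), m).length == 2

    def test_fitch_equals_uniform_sankoff(self, rng):
        """The two algorithms must agree character by character."""
        for _ in range(5):
            m = random_matrix(rng, 6, 10, n_states=4)
            masks, metas = m.state_masks()
            adj = {9: [0, 1, 6], 6: [9, 2, 7], 7: [6, 3, 8], 8: [7, 4, 5],
                   0: [9], 1: [9], 2: [6], 3: [7], 4: [8], 5: [8]}
            rows = {i: i for i in range(6)}
            fitch = fitch_steps_adj(adj, rows, masks)
            sankoff = sankoff_steps_adj(adj, rows, masks,
                                        [m.n_states for m in metas],
                                        [False] * len(metas))
            assert (fitch == sankoff).all()

    def test_ordered_never_cheaper_than_unordered(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 6, 8, n_states=4)
            m.set_ordered([c.index for c in m.characters])
            t = _tree("((t0,t1),(t2,t3),(t4,t5));")
            assert ordered_length(t, m).length >= tree_length(t, m).length


class TestCharStepBounds:
    def test_min_steps_examples(self):
        col = [StateSet.of(0), StateSet.of(1), StateSet.of(2)]
        assert char_min_steps(col) == 2
        col02 = [StateSet.of(0), StateSet.of(2)]
        assert char_min_steps(col02, ordered=True) == 2
        assert char_min_steps(col02) == 1

    def test_min_steps_polymorphism_resolves_cheaply(self):
        col = [StateSet.of(0, 1), StateSet.of(0), StateSet.of(1)]
        # {01} can side with either tip: only the 0/1 conflict remains
        assert char_min_steps(col) == 1

    def test_min_steps_matches_resolution_oracle(self, rng):
        """Minimum over all tip resolutions and all topologies (n=5)."""
        shapes = exhaustive_topologies(5)
        for _ in range(10):
            m = random_matrix(rng, 5, 1, n_states=3, p_missing=0.2, p_poly=0.2)
            col = [m.cells[i][0].states if not m.cells[i][0].is_uncertain
                   else frozenset(range(3)) for i in range(5)]
            oracle = min(oracle_unrooted_length(col, s, 3) for s in shapes)
            assert char_min_steps([m.cells[i][0] for i in range(5)]) == oracle

    def test_max_steps_star_frequencies(self):
        col = [StateSet.of(0)] * 5 + [StateSet.of(1)] * 3
        assert char_max_steps(col) == 3

    def test_max_steps_degenerate(self):
        assert char_max_steps([MISSING, MISSING]) == 0
        assert char_max_steps([StateSet.of(1)] * 4) == 0

    def test_max_steps_is_star_tree_maximum(self, rng):
        """n - modal frequency equals the worst tree's length (n <= 6)."""
        shapes = exhaustive_topologies(6)
        for _ in range(5):
            m = random_matrix(rng, 6, 1, n_states=3, p_missing=0, p_poly=0)
            col = [m.cells[i][0].states for i in range(6)]
            worst = max(oracle_unrooted_length(col, s, 3) for s in shapes)
            assert char_max_steps([m.cells[i][0] for i in range(6)]) == worst

    def test_bounds_bracket_every_topology(self, rng):
        shapes = exhaustive_topologies(6)
        m = random_matrix(rng, 6, 3, n_states=3, p_missing=0.15, p_poly=0.1)
        for j in range(3):
            cells = [m.cells[i][j] for i in range(6)]
            col = [c.states if not c.is_uncertain else frozenset(range(3))
                   for c in cells]
            lo, hi = char_min_steps(cells), char_max_steps(cells)
            for s in shapes:
                assert lo <= oracle_unrooted_length(col, s, 3) <= hi


class TestEnsembleIndices:
    def test_homoplasy_free_gives_ci_one(self):
        ci, ri = ensemble_indices(5, 5, 9)
        assert ci == 1.0 and ri == 1.0

    def test_toy_values(self):
        ci, ri = ensemble_indices(3, 2, 4)
        assert round(ci, 2) == 0.67 and ri == 0.5

    def test_degenerate_conventions(self):
        assert ensemble_indices(0, 0, 0) == (1.0, 1.0)

    def test_inconsistent_sums_rejected(self):
        with pytest.raises(ScoringError):
            ensemble_indices(1, 2, 4)

    def test_score_tree_assembles_indices(self, rng):
        m = random_matrix(rng, 6, 10, n_states=3)
        s = score_tree(_tree("((t0,t1),(t2,t3),(t4,t5));"), m)
        assert s.min_sum <= s.length <= s.max_sum
        assert s.length == sum(s.per_char)
        ci, ri = ensemble_indices(s.length, s.min_sum, s.max_sum)
        assert (s.ci, s.ri) == (ci, ri)
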