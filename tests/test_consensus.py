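"""Consensus construction against set-counting oracles, and Bremer support
against exhaustive search."""

import pytest

from parsimonia.consensus import (ConsensusError, bremer_support,
                                  majority_consensus, strict_consensus)
from parsimonia.parsimony import tree_length
from parsimonia.search import branch_and_bound, enumerate_suboptimal
from parsimonia.trees import Tree

from conftest import (exhaustive_topologies, matrix_from_strings,
                      oracle_unrooted_length, random_matrix, topology_splits)


def _t(nwk):
    return Tree.from_newick(nwk)


class TestStrictConsensus:
    def test_identical_trees_give_that_tree(self):
        trees = [_t("((A,B),(C,D),E);")] * 3
        ct = strict_consensus(trees)
        assert ct.tree.bipartitions() == trees[0].bipartitions()

    def test_single_rotation_collapses_conflict(self):
        t1 = _t("(((A,B),C),D,E);")
        t2 = _t("(((A,C),B),D,E);")
        ct = strict_consensus([t1, t2])
        # brute-force intersection oracle; splits are stored as the side not
        # containing the reference taxon A, so clade ABC appears as split DE
        assert ct.tree.bipartitions() == t1.bipartitions() & t2.bipartitions()
        assert ct.tree.bipartitions() == frozenset({frozenset("DE")})

    def test_leaf_set_mismatch_is_error(self):
        with pytest.raises(ConsensusError):
            strict_consensus([_t("(A,B,C);"), _t("(A,B,D);")])

    def test_input_order_invariance(self, rng):
        m = random_matrix(rng, 6, 5, n_states=2)
        res = branch_and_bound(m, collapse_rule="none")
        fwd = strict_consensus(res.trees).tree.bipartitions()
        rev = strict_consensus(res.trees[::-1]).tree.bipartitions()
        assert fwd == rev

    def test_consensus_scored_with_polytomy_rule(self, rng):
        m = random_matrix(rng, 6, 8, n_states=3)
        res = branch_and_bound(m, collapse_rule="none")
        ct = strict_consensus(res.trees, matrix=m)
        assert ct.score.length >= res.best_length
        assert 0 < ct.score.ci <= 1 and 0 <= ct.score.ri <= 1

    def test_outgroup_rooting_is_display_only(self, rng):
        m = random_matrix(rng, 6, 8, n_states=3)
        res = branch_and_bound(m, collapse_rule="none")
        plain = strict_consensus(res.trees, matrix=m)
        rooted = strict_consensus(res.trees, matrix=m, outgroup="t0")
        assert rooted.tree.root.children[0].label == "t0"
        assert plain.score.length == rooted.score.length


class TestMajorityConsensus:
    def test_clade_in_all_trees_is_100(self):
        trees = [_t("((A,B),(C,D),E);")] * 4
        ct = majority_consensus(trees)
        assert all(s.percent == 100.0 for s in ct.clades.values())

    def test_two_of_three_included_at_67(self):
        trees = [_t("(((A,B),C),D,E);"), _t("(((A,B),C),D,E);"),
                 _t("(((A,C),B),D,E);")]
        ct = majority_consensus(trees)
        ab_as_split = frozenset("CDE")  # the side away from reference taxon A
        assert ab_as_split in ct.clades
        assert round(ct.clades[ab_as_split].percent) == 67

    def test_exactly_half_excluded(self):
        trees = [_t("((A,B),(C,D),E);"), _t("((A,C),(B,D),E);")]
        ct = majority_consensus(trees)
        assert len(ct.clades) == 0

    def test_strict_clades_subset_of_majority(self, rng):
        m = random_matrix(rng, 7, 6, n_states=2)
        res = branch_and_bound(m, collapse_rule="none")
        strict = strict_consensus(res.trees).tree.bipartitions()
        major = majority_consensus(res.trees).tree.bipartitions()
        assert strict <= major

    def test_counting_matches_oracle(self, rng):
        m = random_matrix(rng, 6, 5, n_states=2)
        res = branch_and_bound(m, collapse_rule="none")
        counts = {}
        for t in res.trees:
            for s in t.bipartitions():
                counts[s] = counts.get(s, 0) + 1
        ct = majority_consensus(res.trees)
        n = len(res.trees)
        expected = {s: 100 * c / n for s, c in counts.items() if c / n > 0.5}
        assert set(ct.clades) == set(expected)
        for clade, sup in ct.clades.items():
            assert sup.percent == pytest.approx(expected[clade])


class TestBremer:
    def test_matches_exhaustive_oracle(self, rng):
        """Per-clade decay equals min-length-without-clade minus optimum,
        scored over all 15 five-taxon topologies."""
        for _ in range(5):
            m = random_matrix(rng, 5, 8, n_states=3)
            cols = [[m.cells[i][j].states if not m.cells[i][j].is_uncertain
                     else frozenset(range(3)) for i in range(5)]
                    for j in range(m.n_chars)]
            scored = []
            for shape in exhaustive_topologies(5):
                L = sum(oracle_unrooted_length(col, shape, 3) for col in cols)
                scored.append((topology_splits(shape, 5), L))
            best = min(l for _, l in scored)

            res = branch_and_bound(m, collapse_rule="none")
            slack = 6
            sub = enumerate_suboptimal(m, slack=slack)
            ct = strict_consensus(res.trees)
            ct = bremer_support(m, ct, sub, slack)
            idx = {t: i for i, t in enumerate(m.taxa)}
            for clade, sup in ct.clades.items():
                split = frozenset(idx[x] for x in clade)
                if 0 in split:
                    split = frozenset(range(5)) - split
                without = [l for s, l in scored if split not in s]
                expected = min(without) - best
                assert sup.bremer == expected
                assert not sup.bremer_is_lower_bound

    def test_clade_absent_from_an_mpt_scores_zero(self):
        # two characters in direct conflict -> two MPTs on 4 taxa; with a
        # fifth stabilising taxon the consensus keeps the shared clade only
        m = matrix_from_strings({"A": "00", "B": "01", "C": "10", "D": "11",
                                 "E": "11"})
        res = branch_and_bound(m, collapse_rule="none")
        sub = enumerate_suboptimal(m, slack=1)
        ct = bremer_support(m, strict_consensus(res.trees), sub, 1)
        for sup in ct.clades.values():
            assert sup.bremer >= 1  # strict clades survive by definition

    def test_lower_bound_marker_when_slack_too_small(self):
        # a clade supported by 3 clean characters cannot decay within slack 1
        m = matrix_from_strings({"A": "000", "B": "000", "C": "111",
                                 "D": "111", "E": "111"})
        res = branch_and_bound(m, collapse_rule="none")
        sub = enumerate_suboptimal(m, slack=1)
        ct = bremer_support(m, strict_consensus(res.trees), sub, 1)
        clade = frozenset("CDE") if frozenset("CDE") in ct.clades else frozenset("AB")
        sup = ct.clades[clade]
        assert sup.bremer == 2 and sup.bremer_is_lower_bound
        assert ">=2" in ct.clade_table()["bremer"].astype(str).tolist()[0]

    def test_bremer_monotone_in_slack(self, rng):
        m = random_matrix(rng, 6, 8, n_states=2)
        res = branch_and_bound(m, collapse_rule="none")
        values = {}
        for slack in (1, 3, 5):
            sub = enumerate_suboptimal(m, slack=slack)
            ct = bremer_support(m, strict_consensus(res.trees), sub, slack)
            values[slack] = {c: s.bremer for c, s in ct.clades.items()}
        for clade in values[1]:
            assert values[1][clade] <= values[3][clade] <= values[5][clade]

    def test_empty_suboptimal_set_is_error(self, rng):
        m = random_matrix(rng, 5, 5, n_states=2)
        res = branch_and_bound(m)
        with pytest.raises(ConsensusError):
            bremer_support(m, strict_consensus(res.trees), [], 3)
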