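"""Fitch optimization: lengths, bounds, ensemble indices, ancestral sets."""

import random

import numpy as np
import pytest

import parsiphy as pp
from parsiphy.fitch import ancestral_state_sets, ensemble_indices, round3
from parsiphy.search import stepwise_addition
from parsiphy.tree import parse_newick, reroot_on_outgroup
from conftest import enumerate_topologies, exhaustive_min_steps, make_matrix, random_matrix


class TestFitchLength:
    def test_constant_column_is_free(self):
        m = make_matrix({"A": "0", "B": "0", "C": "0", "D": "0"})
        t = parse_newick("((A,B),(C,D));")
        assert pp.fitch_length(t, m).total == 0

    def test_clean_split_costs_one(self):
        m = make_matrix({"A": "0", "B": "0", "C": "1", "D": "1"})
        t = parse_newick("((A,B),(C,D));")
        assert pp.fitch_length(t, m).total == 1

    def test_incongruent_character_costs_two(self):
        # character 2 splits (A,C)|(B,D): on ((A,B),(C,D)) it needs 2 steps
        m = make_matrix({"A": "00", "B": "01", "C": "10", "D": "11"})
        t = parse_newick("((A,B),(C,D));")
        assert list(pp.fitch_length(t, m).per_char) == [1, 2]

    def test_matches_exhaustive_assignment_minimum(self):
        """Fitch equals brute force over internal labelings (random 7-taxon)."""
        rng = random.Random(11)
        for trial in range(6):
            m = random_matrix(rng, 7, 5, k=3, missing=0.15)
            t = stepwise_addition(m, seed=trial)
            oracle = exhaustive_min_steps(t, m)
            score = pp.fitch_length(t, m)
            assert np.array_equal(score.per_char, oracle)

    def test_bit_parallel_equals_scalar_on_fixture_tree(self, packaged):
        t = stepwise_addition(packaged, seed=0)
        fast = pp.fitch_length(t, packaged)
        slow = pp.fitch_length_scalar(t, packaged)
        assert fast.total == slow.total
        assert np.array_equal(fast.per_char, slow.per_char)

    def test_missing_leaf_row_rejected(self):
        m = make_matrix({"A": "0", "B": "1", "C": "0"})
        t = parse_newick("((A,B),(C,Z));")
        with pytest.raises(KeyError, match="Z"):
            pp.fitch_length(t, m)


class TestBounds:
    def test_worked_column(self):
        # 5 x state0, 3 x state1, 2 x '?': m = 1, g = 3
        rows = {f"t{i}": s for i, s in enumerate("00000111??")}
        m = make_matrix(rows)
        mins, maxs = pp.char_bounds(m)
        assert mins[0] == 1
        # recheck g against the star-tree argument: det taxa - modal count
        assert maxs[0] == 8 - 5

    def test_constant_column(self):
        m = make_matrix({"A": "0", "B": "0", "C": "0"})
        mins, maxs = pp.char_bounds(m)
        assert mins[0] == 0 and maxs[0] == 0

    def test_three_state_column(self):
        rows = {f"t{i}": s for i, s in enumerate("001122")}
        mins, _ = pp.char_bounds(make_matrix(rows))
        assert mins[0] == 2  # k - 1

    def test_g_is_star_tree_length_small_instances(self):
        """g_i equals the maximum Fitch length over all tree shapes (n=6)."""
        rng = random.Random(2)
        m = random_matrix(rng, 6, 4, k=3, missing=0.2)
        _, maxs = pp.char_bounds(m)
        observed_max = np.zeros(m.n_char, dtype=np.int64)
        for t in enumerate_topologies(m.taxa):
            np.maximum(
                observed_max, pp.fitch_length(t, m).per_char, out=observed_max
            )
        assert np.array_equal(maxs, observed_max)

    def test_bounds_sandwich_observed_steps(self):
        """m_i <= s_i <= g_i over many random (tree, character) draws."""
        rng = random.Random(9)
        checked = 0
        while checked < 1000:
            m = random_matrix(rng, rng.randrange(5, 10), 8, k=3, missing=0.1)
            t = stepwise_addition(m, seed=rng.randrange(2**31))
            mins, maxs = pp.char_bounds(m)
            s = pp.fitch_length(t, m).per_char
            assert (mins <= s).all() and (s <= maxs).all()
            checked += m.n_char


class TestEnsembleIndices:
    def test_no_homoplasy_gives_ci_one(self):
        m = make_matrix({"A": "00", "B": "01", "C": "11", "D": "11"})
        mins, _ = pp.char_bounds(m)
        e = ensemble_indices(int(mins.sum()), m)
        assert e.ci == 1.0

    def test_zero_length_flagged(self):
        m = make_matrix({"A": "0", "B": "0", "C": "0"})
        e = ensemble_indices(0, m)
        assert not e.ci_defined and not e.ri_defined

    def test_packaged_statistics_at_printed_optima(self, packaged, groups):
        e = ensemble_indices(236, packaged, variant="all")
        assert (round3(e.ci), round3(e.ri)) == (0.229, 0.715)
        sub = pp.subset_matrix(packaged, groups["arminidae"])
        e2 = ensemble_indices(133, sub, variant="all")
        assert round3(e2.ci) == 0.301

    def test_informative_variant_differs(self, packaged):
        a = ensemble_indices(236, packaged, variant="all")
        b = ensemble_indices(235, packaged, variant="informative")
        assert (a.M, a.G) != (b.M, b.G)


class TestAncestralStates:
    def test_uniform_clade_reconstructs_its_state(self):
        m = make_matrix({"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),(C,(D,E)));"), ["E"])
        anc = ancestral_state_sets(t, m, 1)
        clade = t.find_clade({"A", "B"})
        assert anc.final[id(clade)] == frozenset({1})

    def test_cherry_preliminary_union(self):
        m = make_matrix({"A": "0", "B": "1", "C": "0", "D": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),(C,D));"), ["D"])
        anc = ancestral_state_sets(t, m, 1)
        cherry = t.find_clade({"A", "B"})
        assert anc.prelim[id(cherry)] == frozenset({0, 1})

    def test_requires_rooted_tree(self):
        m = make_matrix({"A": "0", "B": "1", "C": "0", "D": "0"})
        t = parse_newick("(A,B,(C,D));")  # basal trichotomy: unrooted
        assert not t.rooted
        with pytest.raises(ValueError, match="rooted"):
            ancestral_state_sets(t, m, 1)

    def test_final_sets_are_subsets_of_states_in_some_mpr(self):
        """Every ACCTRAN state assignment lies inside the final (MPR) sets."""
        rng = random.Random(4)
        for trial in range(5):
            m = random_matrix(rng, 7, 6, k=3)
            t = reroot_on_outgroup(stepwise_addition(m, seed=trial), [m.taxa[0]])
            smap = pp.map_synapomorphies(t, m, resolution="acctran")
            from parsiphy.mapping import _backtrace

            states = _backtrace(t, m, m.state_sets(), prefer_change=True)
            for j in range(1, m.n_char + 1):
                anc = ancestral_state_sets(t, m, j)
                for node in t.nodes():
                    if not node.is_leaf:
                        assert int(states[id(node)][j - 1]) in anc.final[id(node)]


class TestScoreTable:
    def test_table_shape_and_consistency(self, packaged):
        t = stepwise_addition(packaged, seed=3)
        df = pp.character_score_table(t, packaged)
        assert len(df) == 43
        assert (df["min_steps"] <= df["steps"]).all()
        assert (df["steps"] <= df["max_steps"]).all()
        assert df["name"].iloc[0] == "Gill"
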