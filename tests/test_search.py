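"""Tree search: stepwise addition, branch swapping, branch and bound."""

import random

import numpy as np
import pytest

import parsiphy as pp
from parsiphy.search import (
    BNB_GUARD,
    FlatTree,
    SearchConfig,
    branch_and_bound,
    heuristic_search,
    stepwise_addition,
)
from parsiphy.tree import bipartitions
from conftest import enumerate_topologies, make_matrix, random_matrix


def sim_instance(seed, n_taxa=8, n_char=30, **kw):
    cfg = pp.SimConfig(n_taxa=n_taxa, n_char=n_char, seed=seed,
                       expected_changes=kw.pop("rate", 1.0), **kw)
    tree = pp.simulate_tree(cfg)
    m, log = pp.simulate_matrix(tree, cfg)
    return tree, m, log


def split_key(tree):
    return frozenset(bp.side for bp in bipartitions(tree))


class TestStepwise:
    def test_three_taxa_is_the_unique_topology(self):
        m = make_matrix({"A": "01", "B": "00", "C": "11"})
        t = stepwise_addition(m, seed=0)
        assert t.n_leaves == 3
        mins, _ = pp.char_bounds(m)
        assert pp.fitch_length(t, m).total == mins.sum()

    def test_same_seed_same_tree(self):
        _, m, _ = sim_instance(5)
        a = stepwise_addition(m, seed=42)
        b = stepwise_addition(m, seed=42)
        assert split_key(a) == split_key(b)

    def test_different_seed_usually_differs(self):
        rng = random.Random(0)
        m = random_matrix(rng, 10, 15)
        keys = {split_key(stepwise_addition(m, seed=s)) for s in range(8)}
        assert len(keys) > 1

    def test_stepwise_is_near_optimal_on_clean_data(self):
        """Greedy addition finds the exact optimum for most seeds (>= 90%).

        Uses the clean-data world (8 taxa, 200 characters, one expected
        change per character) under which recovery rates are defined.
        """
        hits = 0
        trials = 40
        for seed in range(trials):
            _, m, _ = sim_instance(seed, n_taxa=8, n_char=200)
            exact = branch_and_bound(m).best_length
            t = stepwise_addition(m, seed=seed * 7 + 1)
            hits += pp.fitch_length(t, m).total == exact
        assert hits >= 0.9 * trials


class TestBranchAndBound:
    def test_four_taxa_all_topologies(self):
        m = make_matrix({"A": "00", "B": "01", "C": "10", "D": "11"})
        res = branch_and_bound(m)
        scores = {
            pp.fitch_length(t, m).total for t in enumerate_topologies(m.taxa)
        }
        assert res.best_length == min(scores)

    def test_matches_full_enumeration_eight_taxa(self):
        """Optimal set identical to scoring all 10395 topologies."""
        rng = random.Random(1)
        m = random_matrix(rng, 8, 12, k=3, missing=0.1)
        res = branch_and_bound(m, cfg=SearchConfig(collapse_policy="none"))
        best = None
        optimal = set()
        for t in enumerate_topologies(m.taxa):
            L = pp.fitch_length_scalar(t, m).total
            if best is None or L < best:
                best, optimal = L, {split_key(t)}
            elif L == best:
                optimal.add(split_key(t))
        assert res.best_length == best
        assert {split_key(t) for t in res.trees} == optimal

    def test_generating_topology_recovered_from_clean_data(self):
        tree, m, _ = sim_instance(3, n_taxa=7, n_char=60)
        res = branch_and_bound(m, cfg=SearchConfig(collapse_policy="none"))
        assert split_key(tree) in {split_key(t) for t in res.trees}

    def test_guard_rail(self, packaged):
        with pytest.raises(ValueError, match="heuristic_search"):
            branch_and_bound(packaged)
        assert BNB_GUARD == 12

    def test_slack_pool_contains_suboptimal_trees(self):
        rng = random.Random(5)
        m = random_matrix(rng, 7, 10)
        res = branch_and_bound(m, slack=2)
        lengths = res.replicate_log[0]["lengths"]
        assert min(lengths) == res.best_length
        assert max(lengths) <= res.best_length + 2
        assert len(lengths) > len(
            [L for L in lengths if L == res.best_length]
        )


class TestHeuristicSearch:
    def test_reproducible(self):
        _, m, _ = sim_instance(9, n_taxa=10, n_char=20, missing_frac=0.1)
        cfg = SearchConfig(replicates=2, seed=123, patience=40, maxtrees=20)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.best_length == b.best_length
        assert [split_key(t) for t in a.trees] == [split_key(t) for t in b.trees]
        assert a.replicate_log == b.replicate_log

    @pytest.mark.parametrize("swap", ["nni", "spr", "tbr"])
    def test_swap_never_worse_than_start(self, swap):
        _, m, _ = sim_instance(2, n_taxa=10, n_char=15, missing_frac=0.2)
        cfg = SearchConfig(replicates=2, seed=1, swap=swap, patience=30, maxtrees=10)
        res = heuristic_search(m, cfg)
        for entry in res.replicate_log:
            assert entry["final_length"] <= entry["start_length"]

    def test_finds_exact_optimum_small_instances(self):
        for seed in range(8):
            _, m, _ = sim_instance(seed + 50, n_taxa=8, n_char=25, missing_frac=0.1)
            exact = branch_and_bound(m).best_length
            res = heuristic_search(
                m, SearchConfig(replicates=2, seed=seed, patience=40, maxtrees=10)
            )
            assert res.best_length == exact

    def test_retained_trees_all_score_best_length(self):
        _, m, _ = sim_instance(4, n_taxa=9, n_char=15, missing_frac=0.2)
        res = heuristic_search(
            m, SearchConfig(replicates=2, seed=3, patience=40,
                            maxtrees=30, collapse_policy="none")
        )
        keys = set()
        for t in res.trees:
            assert pp.fitch_length(t, m).total == res.best_length
            keys.add(split_key(t))
        assert len(keys) == len(res.trees)  # no duplicate topologies

    def test_maxtrees_cap_flagged_not_fatal(self):
        _, m, _ = sim_instance(6, n_taxa=10, n_char=8, missing_frac=0.3)
        res = heuristic_search(
            m, SearchConfig(replicates=1, seed=0, patience=20, maxtrees=2)
        )
        assert isinstance(res.hit_maxtrees, bool)

    def test_constrained_search_respects_forbidden_clade(self):
        from parsiphy.tree import Bipartition

        tree, m, _ = sim_instance(8, n_taxa=9, n_char=40)
        free = heuristic_search(m, SearchConfig(replicates=2, seed=1, patience=30))
        # forbid a clade present in the optimal trees
        some = bipartitions(free.trees[0])
        clade = sorted(some, key=lambda bp: len(bp.side))[0]
        res = heuristic_search(
            m,
            SearchConfig(replicates=2, seed=2, patience=60, collapse_policy="none"),
            forbid=clade,
        )
        assert res.best_length >= free.best_length
        for t in res.trees:
            assert clade not in bipartitions(t)


class TestFlatTree:
    def test_phylo_round_trip(self):
        rng = random.Random(7)
        m = random_matrix(rng, 12, 5)
        ft = stepwise_addition(m, seed=5, return_flat=True)
        back = FlatTree.from_phylo(ft.to_phylo(m.taxa), m.taxa)
        assert back.topology_key() == ft.topology_key()

    def test_contains_split_agrees_with_bipartitions(self):
        from parsiphy.search import split_mask

        rng = random.Random(3)
        m = random_matrix(rng, 8, 5)
        ft = stepwise_addition(m, seed=1, return_flat=True)
        tree = ft.to_phylo(m.taxa)
        for bp in bipartitions(tree):
            assert ft.contains_split(split_mask(bp.side, m.taxa))
        absent = frozenset(m.taxa[:4])
        from parsiphy.tree import Bipartition

        bp = Bipartition(absent, frozenset(m.taxa))
        expected = bp in bipartitions(tree)
        assert ft.contains_split(split_mask(bp.side, m.taxa)) == expected
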