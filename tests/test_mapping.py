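"""Synapomorphy mapping, ACCTRAN/DELTRAN, homoplasy flags, collapsing."""

import random

import numpy as np
import pytest

import parsiphy as pp
from parsiphy.mapping import (
    clade_diagnostics,
    collapse_zero_length_branches,
    map_synapomorphies,
)
from parsiphy.search import stepwise_addition
from parsiphy.tree import bipartitions, parse_newick, reroot_on_outgroup
from conftest import make_matrix, random_matrix


def rooted_instance(seed, n_taxa=8, n_char=12, k=3):
    rng = random.Random(seed)
    m = random_matrix(rng, n_taxa, n_char, k=k)
    t = reroot_on_outgroup(stepwise_addition(m, seed=seed), [m.taxa[0]])
    return m, t


class TestMapping:
    def test_single_clade_apomorphy_maps_to_stem(self):
        m = make_matrix({"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),E));"), ["A"])
        smap = map_synapomorphies(t, m, resolution="acctran")
        assert smap.total_changes == 1
        (entry,) = smap.entries
        assert entry.clade == frozenset({"C", "D"})
        assert (entry.from_state, entry.to_state) == (0, 1)
        assert not entry.homoplastic
        assert smap.homoplastic_chars == frozenset()

    @pytest.mark.parametrize("resolution", ["acctran", "deltran"])
    def test_total_changes_equal_fitch_length(self, resolution):
        """Any single full resolution maps exactly the tree length."""
        for seed in range(12):
            m, t = rooted_instance(seed)
            smap = map_synapomorphies(t, m, resolution=resolution)
            assert smap.total_changes == pp.fitch_length(t, m).total

    def test_per_character_conservation(self):
        m, t = rooted_instance(33)
        smap = map_synapomorphies(t, m, resolution="deltran")
        steps = pp.fitch_length(t, m).per_char
        for j in range(m.n_char):
            mapped = sum(1 for e in smap.entries if e.char_index == j + 1)
            assert mapped == steps[j]

    def test_unambiguous_subset_of_both_resolutions(self):
        for seed in range(8):
            m, t = rooted_instance(seed + 100)
            keys = lambda smap: {(e.clade, e.char_index) for e in smap.entries}
            un = keys(map_synapomorphies(t, m, resolution="unambiguous"))
            acc = keys(map_synapomorphies(t, m, resolution="acctran"))
            del_ = keys(map_synapomorphies(t, m, resolution="deltran"))
            assert un <= acc and un <= del_

    def test_homoplasy_flag_follows_extra_steps(self):
        # character needs 2 steps on this tree but its minimum is 1
        m = make_matrix({"A": "0", "B": "1", "C": "0", "D": "1", "E": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),E));"), ["A"])
        smap = map_synapomorphies(t, m, resolution="acctran")
        assert smap.homoplastic_chars == frozenset({1})
        assert all(e.homoplastic for e in smap.entries)

    def test_acctran_prefers_rootward_deltran_tipward(self):
        # state 1 in clade (C,D) with an equivocal branch above it:
        # ACCTRAN places the change no later than DELTRAN on every path
        m = make_matrix({"A": "0", "B": "?", "C": "1", "D": "1"})
        t = reroot_on_outgroup(parse_newick("((A,B),(C,D));"), ["A"])
        acc = map_synapomorphies(t, m, resolution="acctran")
        dl = map_synapomorphies(t, m, resolution="deltran")
        acc_sizes = sorted(len(e.clade) for e in acc.entries)
        dl_sizes = sorted(len(e.clade) for e in dl.entries)
        assert acc_sizes >= dl_sizes  # earlier change = larger clade below it

    def test_requires_rooted_tree(self):
        m = make_matrix({"A": "0", "B": "1", "C": "0", "D": "0"})
        with pytest.raises(ValueError, match="rooted"):
            map_synapomorphies(parse_newick("(A,B,(C,D));"), m)

    def test_polytomy_warns(self):
        m = make_matrix({"A": "0", "B": "1", "C": "0", "D": "0"})
        t = parse_newick("((A,B,C),D);")
        t.rooted = True
        with pytest.warns(UserWarning, match="polytom"):
            map_synapomorphies(t, m, resolution="acctran")


class TestCladeDiagnostics:
    def test_stem_entries_only(self):
        m = make_matrix({"A": "00", "B": "00", "C": "11", "D": "11", "E": "00"})
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),E));"), ["A"])
        smap = map_synapomorphies(t, m)
        entries = clade_diagnostics(smap, frozenset({"C", "D"}))
        assert {e.char_index for e in entries} == {1, 2}
        assert entries[0].char_name == "char1"

    def test_clade_without_changes_is_empty(self):
        m = make_matrix({"A": "0", "B": "0", "C": "0", "D": "1", "E": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),E));"), ["A"])
        smap = map_synapomorphies(t, m)
        assert clade_diagnostics(smap, frozenset({"C", "D"})) == []

    def test_absent_clade_rejected(self):
        m = make_matrix({"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"})
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),E));"), ["A"])
        smap = map_synapomorphies(t, m)
        with pytest.raises(KeyError):
            clade_diagnostics(smap, frozenset({"B", "C"}))

    def test_hand_computed_six_taxon_instance(self):
        """Changes agree with a by-hand Fitch down/up pass.

        On ((A,B),((C,D),(E,F))) rooted on A, char 1 (C=D=1, rest 0) and
        char 2 (E=F=1, rest 0) each cost one step that every reconstruction
        must place on the respective two-taxon stem.  Char 3 (C=D=1, E=F=2)
        is ambiguous: the 0->1 change can sit on the (C,D) stem or above the
        (C,D,E,F) ancestor, so it contributes nothing unambiguous.
        """
        m = make_matrix(
            {"A": "000", "B": "000", "C": "101", "D": "101", "E": "012", "F": "012"}
        )
        t = reroot_on_outgroup(parse_newick("((A,B),((C,D),(E,F)));"), ["A"])
        smap = map_synapomorphies(t, m, resolution="unambiguous")
        got = {(e.clade, e.char_index, e.from_state, e.to_state) for e in smap.entries}
        assert got == {
            (frozenset({"C", "D"}), 1, 0, 1),
            (frozenset({"E", "F"}), 2, 0, 1),
        }
        # the ambiguous char 3 still maps fully under a single resolution
        acc = map_synapomorphies(t, m, resolution="acctran")
        assert sum(e.char_index == 3 for e in acc.entries) == 2


class TestCollapsing:
    def test_forced_branches_survive_min_collapse(self):
        m = make_matrix({"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"})
        t = parse_newick("((A,B),((C,D),E));")
        ct = collapse_zero_length_branches(t, m, criterion="min")
        assert pp.fitch_length(ct, m).total == pp.fitch_length(t, m).total
        from parsiphy.tree import Bipartition

        assert Bipartition({"C", "D"}, t.taxa) in bipartitions(ct)

    def test_unsupported_branch_collapses(self):
        # no character supports (A,B): its stem can always be zero-length
        m = make_matrix({"A": "0", "B": "0", "C": "0", "D": "1", "E": "1"})
        t = parse_newick("(((A,B),C),(D,E));")
        ct = collapse_zero_length_branches(t, m, criterion="min")
        from parsiphy.tree import Bipartition

        assert Bipartition({"A", "B"}, t.taxa) not in bipartitions(ct)

    def test_max_collapse_is_less_aggressive(self):
        rng = random.Random(3)
        for seed in range(5):
            m = random_matrix(rng, 8, 10)
            t = stepwise_addition(m, seed=seed)
            mn = collapse_zero_length_branches(t, m, criterion="min")
            mx = collapse_zero_length_branches(t, m, criterion="max")
            assert bipartitions(mn) <= bipartitions(mx) <= bipartitions(t)
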