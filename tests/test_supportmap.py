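import itertools

import numpy as np
import pytest

from archdc.io_phylo import read_newick
from archdc.supportmap import (Bipartition, SupportMapError, bipartitions,
                               classify_branch, maxdiff, root_bipartition,
                               support_grid, transfer_root)

from conftest import (all_unrooted_topologies, newick_to_dendropy,
                      topology_bipartitions, topology_to_newick)


def bip(a, b):
    return Bipartition.from_blocks(set(a), set(b))


class TestBipartition:
    def test_counts_n_minus_three(self):
        assert len(bipartitions(read_newick("((A,B),(C,D));"))) == 1
        six = read_newick("(((A,B),C),(D,(E,F)));")
        assert len(bipartitions(six)) == 3

    def test_exhaustive_edge_enumeration_oracle(self):
        """Bipartition extraction agrees with independent enumeration on
        every unrooted topology over 7 leaves."""
        labels = list("ABCDEFG")
        for topo in all_unrooted_topologies(labels):
            tree = newick_to_dendropy(topology_to_newick(topo))
            mine = {frozenset(b.blocks) for b in bipartitions(tree)}
            oracle = topology_bipartitions(topo)
            assert mine == oracle

    def test_restrict_identity_and_degenerate(self):
        b = bip("AB", "CD")
        assert b.restrict({"A", "B", "C", "D"}) == b
        assert b.restrict({"A", "B"}) is None
        assert b.restrict({"A", "C"}).is_trivial()

    def test_restriction_commutes_with_block_swap(self):
        b1 = Bipartition.from_blocks({"A", "B"}, {"C", "D", "E"})
        b2 = Bipartition.from_blocks({"C", "D", "E"}, {"A", "B"})
        shared = {"A", "C", "D"}
        assert b1 == b2 and b1.restrict(shared) == b2.restrict(shared)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(SupportMapError):
            Bipartition.from_blocks({"A", "B"}, {"B", "C"})


def co_displayable(b1, b2, labels):
    """Oracle: two bipartitions are compatible iff some unrooted tree
    displays both (exhaustive tree enumeration)."""
    for topo in all_unrooted_topologies(labels):
        shown = topology_bipartitions(topo)
        if frozenset(b1.blocks) in shown and frozenset(b2.blocks) in shown:
            return True
    return False


class TestCompatibility:
    def test_four_intersection_rule_matches_co_displayability(self):
        """The four-intersection compatibility test agrees with the
        exhaustive 'both displayable on one tree' oracle over 6 taxa."""
        labels = list("ABCDEF")
        nontrivial = []
        for r in range(2, 5):
            for block in itertools.combinations(labels, r):
                b = bip(block, set(labels) - set(block))
                if b not in nontrivial:
                    nontrivial.append(b)
        for b1, b2 in itertools.combinations(nontrivial, 2):
            assert b1.compatible_with(b2) == co_displayable(b1, b2, labels)

    def test_symmetric(self):
        b1, b2 = bip("AB", "CDEF"), bip("AC", "BDEF")
        assert b1.compatible_with(b2) == b2.compatible_with(b1) is False


class TestClassifyBranch:
    ref = bip("AB", "CDE")

    def tree_with_support(self, newick):
        return read_newick(newick)

    def test_matching_high_support_green(self):
        t = self.tree_with_support("((A,B)0.96,(C,D),E);")
        call = classify_branch(self.ref, t)
        assert (call.status, call.category) == ("supported", "green")
        assert call.support == pytest.approx(0.96)

    def test_matching_low_support_light_green(self):
        t = self.tree_with_support("((A,B)0.90,(C,D),E);")
        call = classify_branch(self.ref, t, support_kind="bv")
        assert (call.status, call.category) == ("supported", "light_green")

    def test_conflict_full_support_red(self):
        t = self.tree_with_support("((A,C)1.0,(B,D),E);")
        call = classify_branch(self.ref, t)
        assert (call.status, call.category) == ("conflicting", "red")
        assert call.support == 1.0

    def test_conflict_weak_support_light_red(self):
        t = self.tree_with_support("((A,C)0.5,(B,D)0.3,E);")
        call = classify_branch(self.ref, t)
        assert (call.status, call.category) == ("conflicting", "light_red")

    def test_too_few_shared_taxa_absent(self):
        t = self.tree_with_support("((A,B)0.9,(X,Y),Z);")
        call = classify_branch(self.ref, t)
        assert (call.status, call.category) == ("unresolved", "absent")

    def test_conflict_support_is_max_incompatible(self):
        """Conflict support = the strongest incompatible branch, checked
        against the four-intersection definition on an enumerated case."""
        t = self.tree_with_support("((A,C)0.7,((B,D)0.6,E));")
        shared = {"A", "B", "C", "D", "E"}
        restricted = self.ref.restrict(shared)
        incompat = [s for b, s in bipartitions(t).items()
                    if not b.restrict(shared).compatible_with(restricted)]
        call = classify_branch(self.ref, t)
        assert call.support == pytest.approx(max(incompat))

    def test_never_both_red_and_green(self):
        for newick in ("((A,B)0.99,(C,D),E);", "((A,C)0.99,(B,D),E);",
                       "((A,B)0.2,(C,D),E);"):
            call = classify_branch(self.ref, read_newick(newick))
            assert call.category in ("green", "light_green", "red", "light_red")

    def test_threshold_validation(self):
        t = self.tree_with_support("((A,B)0.9,(C,D),E);")
        with pytest.raises(SupportMapError):
            classify_branch(self.ref, t, pp_threshold=1.5)


class TestSupportGrid:
    def test_reference_against_itself_all_green(self):
        ref = read_newick("(((A,B)1.0,C)1.0,(D,(E,F)1.0)1.0);")
        table = support_grid(ref, [("self", ref, "pp")])
        assert set(table.categories()["self"]) == {"green"}

    def test_missing_clade_reported_absent(self):
        ref = read_newick("(((A,B)1.0,C)1.0,(D,(E,F)1.0)1.0);")
        other = read_newick("((A,B)0.9,(C,D),X);")  # E,F absent
        table = support_grid(ref, [("other", other, "pp")])
        assert "absent" in set(table.categories()["other"])

    def test_hand_classified_fixture(self):
        """Three analyses against a 6-leaf reference reproduce the
        hand-derived category grid."""
        ref = read_newick("(((A,B)1.0,C)1.0,((D,E)1.0,F)1.0);")
        same = read_newick("(((A,B)0.97,C)0.99,((D,E)0.98,F)0.96);")
        weak = read_newick("(((A,B)0.5,C)0.94,((D,E)0.6,F)0.9);")
        confl = read_newick("(((A,C)0.99,B)0.99,((D,E)0.2,F)0.9);")
        table = support_grid(ref, [("same", same, "pp"), ("weak", weak, "pp"),
                                   ("confl", confl, "pp")])
        cats = table.categories()
        ab = bip("AB", "CDEF").branch_id()
        de = bip("DE", "ABCF").branch_id()
        abc = bip("ABC", "DEF").branch_id()
        assert cats.loc[ab].tolist() == ["green", "light_green", "red"]
        assert cats.loc[de].tolist() == ["green", "light_green", "light_green"]
        assert cats.loc[abc].tolist() == ["green", "light_green", "green"]


class TestMaxdiff:
    def trees(self, *newicks):
        return [read_newick(n) for n in newicks]

    def test_identical_samples_zero(self):
        s = self.trees("((A,B),(C,D),E);", "((A,C),(B,D),E);")
        assert maxdiff(s, s) == 0.0

    def test_opposite_quartets_one(self):
        s1 = self.trees("((A,B),(C,D));", "((A,B),(C,D));")
        s2 = self.trees("((A,C),(B,D));", "((A,C),(B,D));")
        assert maxdiff(s1, s2) == 1.0

    def test_hand_tally_on_mixed_samples(self):
        # sample1: AB|CDE in 3/4 trees; sample2: in 1/4 -> diff 0.5 dominates
        ab = "((A,B),(C,D),E);"
        ac = "((A,C),(B,D),E);"
        s1 = self.trees(ab, ab, ab, ac)
        s2 = self.trees(ab, ac, ac, ac)
        assert maxdiff(s1, s2) == pytest.approx(0.5)

    def test_symmetry_and_triangle_bound(self):
        ab = "((A,B),(C,D),E);"
        ac = "((A,C),(B,D),E);"
        ad = "((A,D),(B,C),E);"
        a = self.trees(ab, ab, ac)
        b = self.trees(ab, ac, ac)
        c = self.trees(ad, ad, ab)
        assert maxdiff(a, b) == maxdiff(b, a)
        assert maxdiff(a, c) <= maxdiff(a, b) + maxdiff(b, c) + 1e-12

    def test_mismatched_universes_rejected(self):
        with pytest.raises(SupportMapError):
            maxdiff(self.trees("((A,B),(C,D));"), self.trees("((A,B),(C,X));"))


class TestTransferRoot:
    def test_self_transfer_round_trips(self):
        rooted = read_newick("((A,B),((C,D),E));", rooted=True)
        unrooted = read_newick("((A,B),((C,D),E));")
        unrooted.is_rooted = False
        back = transfer_root(unrooted, rooted)
        assert root_bipartition(back) == root_bipartition(rooted)

    def test_smaller_reference_roots_supertree(self):
        """A rooted 4-taxon reference places the root on the corresponding
        branch of a 6-taxon tree containing the restricted split."""
        reference = read_newick("((A,B),(C,D));", rooted=True)
        big = read_newick("(((A,X),B),((C,(D,Y))));")
        big.is_rooted = False
        rooted = transfer_root(big, reference)
        sides = {frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in rooted.seed_node.child_nodes()}
        assert frozenset({"A", "X", "B"}) in sides

    def test_conflicting_reference_fails_loudly(self):
        reference = read_newick("((A,C),(B,D));", rooted=True)
        big = read_newick("(((A,B),C),(D,E));")
        big.is_rooted = False
        with pytest.raises(SupportMapError, match="absent from the unrooted"):
            transfer_root(big, reference)

    def test_degenerate_restriction_rejected(self):
        reference = read_newick("((X,Y),(A,B));", rooted=True)
        small = read_newick("((A,B),(C,D),E);")
        small.is_rooted = False
        with pytest.raises(SupportMapError, match="degenerate"):
            transfer_root(small, reference)
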