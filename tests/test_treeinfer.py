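import io
import itertools

import dendropy
import numpy as np
import pytest

from archdc import seqsim, supportmap, treeinfer
from archdc.io_phylo import FamilyAlignment
from archdc.substmodel import lg_model, poisson_model
from archdc.treeinfer import (TreeInferError, bootstrap_support,
                              distance_matrix, estimate_alpha, ml_distance,
                              nj, nj_tree, pruning_loglik, root_with_outgroup)


class TestMlDistance:
    def test_identical_sequences_zero(self):
        assert ml_distance("ACDEFG", "ACDEFG").value == 0.0

    def test_poisson_closed_form(self):
        """Under the Poisson model without rate variation the MLE admits the
        closed form -(19/20) ln(1 - (20/19) p)."""
        model = poisson_model()
        rng = np.random.default_rng(0)
        residues = np.array(list(model.states))
        a = residues[rng.integers(0, 20, 4000)]
        # flip 10% of positions to a different residue
        b = a.copy()
        flip = rng.random(4000) < 0.1
        b[flip] = residues[(np.searchsorted(residues, b[flip]) + 7) % 20]
        sa, sb = "".join(a), "".join(b)
        p = np.mean(a != b)
        closed = -(19 / 20) * np.log(1 - (20 / 19) * p)
        est = ml_distance(sa, sb, model)
        assert est.value == pytest.approx(closed, abs=1e-6)
        assert not est.saturated

    def test_saturated_pair_capped_and_flagged(self):
        model = poisson_model()
        # maximally different: p near 19/20 -> beyond the Poisson horizon
        a = "".join(model.states[i % 20] for i in range(400))
        b = "".join(model.states[(i + 1) % 20] for i in range(400))
        est = ml_distance(a, b, model)
        assert est.saturated and est.value == treeinfer.DEFAULT_DISTANCE_CAP

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(TreeInferError, match="comparable"):
            ml_distance("??", "AC")

    def test_monotone_in_difference_fraction(self):
        model = lg_model(alpha=1.0)
        base = "ACDEFGHIKLMNPQRSTVWY" * 20
        dists = []
        for k in (10, 40, 80):
            mutated = list(base)
            for i in range(k):
                mutated[i * 4] = "W" if mutated[i * 4] != "W" else "Y"
            dists.append(ml_distance(base, "".join(mutated), model).value)
        assert dists[0] < dists[1] < dists[2]


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj(D, ["a", "b", "c"])
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}
        assert len(tree.seed_node.child_nodes()) == 3

    def test_additive_four_taxon_matrix_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj(D, ["a", "b", "c", "d"])
        bips = set(supportmap.bipartitions(tree))
        expected = supportmap.Bipartition.from_blocks({"a", "b"}, {"c", "d"})
        assert bips == {expected}
        # on an additive matrix NJ reproduces the path distances exactly
        dm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (i, x), (j, y) in itertools.combinations(enumerate("abcd"), 2):
            assert dm.distance(taxa[x], taxa[y]) == pytest.approx(D[i, j])

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        spec = seqsim.SpeciesTreeSpec(n_ingroup_taxa=8, seed=5)
        tree = seqsim.simulate_species_tree(spec)
        fam = seqsim.evolve_alignment(tree, seqsim.FamilySpec("f", length=600),
                                      rng=rng)
        ids, D, _ = distance_matrix(fam, lg_model(alpha=1.0))
        t1 = nj(D, ids)
        perm = np.array([3, 1, 7, 0, 6, 2, 5, 4])
        t2 = nj(D[np.ix_(perm, perm)], [ids[i] for i in perm])
        assert set(supportmap.bipartitions(t1)) == set(supportmap.bipartitions(t2))

    def test_agrees_with_dendropy_nj(self):
        """Cross-check against dendropy's independent NJ implementation."""
        rng = np.random.default_rng(2)
        spec = seqsim.SpeciesTreeSpec(n_ingroup_taxa=10, seed=2)
        tree = seqsim.simulate_species_tree(spec)
        fam = seqsim.evolve_alignment(tree, seqsim.FamilySpec("f", length=800),
                                      rng=rng)
        ids, D, _ = distance_matrix(fam, lg_model(alpha=1.0))
        mine = nj(D, ids)

        csv = "," + ",".join(ids) + "\n" + "\n".join(
            ids[i] + "," + ",".join(str(D[i, j]) for j in range(len(ids)))
            for i in range(len(ids)))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv))
        theirs = pdm.nj_tree()
        theirs.is_rooted = False
        assert set(supportmap.bipartitions(mine)) == \
            set(supportmap.bipartitions(theirs))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(TreeInferError):
            nj(np.zeros((2, 2)), ["a", "b"])


@pytest.fixture(scope="module")
def family():
    spec = seqsim.SpeciesTreeSpec(n_ingroup_taxa=8, seed=9,
                                  edge_length_mean=0.08)
    tree = seqsim.simulate_species_tree(spec)
    fam = seqsim.evolve_alignment(tree, seqsim.FamilySpec("f", length=1500),
                                  rng=np.random.default_rng(9))
    return tree, fam


class TestBootstrap:

    def test_single_replicate_supports_binary(self, family):
        _, fam = family
        tree = bootstrap_support(fam, lg_model(alpha=1.0), n_replicates=1, seed=3)
        supports = [n.support for n in tree.preorder_node_iter()
                    if getattr(n, "support", None) is not None]
        assert supports and set(supports) <= {0.0, 1.0}

    def test_seed_reproducibility(self, family):
        _, fam = family
        m = lg_model(alpha=1.0)
        t1 = bootstrap_support(fam, m, n_replicates=10, seed=42)
        t2 = bootstrap_support(fam, m, n_replicates=10, seed=42)
        b1, b2 = supportmap.bipartitions(t1), supportmap.bipartitions(t2)
        assert b1 == b2

    def test_true_clades_highly_supported_on_clean_data(self, family):
        true_tree, fam = family
        inferred = bootstrap_support(fam, lg_model(alpha=1.0),
                                     n_replicates=30, seed=1)
        inf_bips = supportmap.bipartitions(inferred)
        true_bips = set(supportmap.bipartitions(true_tree))
        matched = {b: s for b, s in inf_bips.items() if b in true_bips}
        assert matched  # the clean simulation recovers true branches...
        assert np.mean([s for s in matched.values()]) > 0.8
        # ...and every true branch outranks every conflicting one
        conflict = [s for b, s in inf_bips.items() if b not in true_bips]
        if conflict:
            assert min(matched.values()) >= max(conflict)


def brute_force_loglik(tree, matrix, model):
    """Exhaustive sum over all internal-node state assignments."""
    rates = model.category_rates()
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    seq_of = dict(zip(matrix.ids, matrix.seqs))
    state_of = {c: i for i, c in enumerate(model.states)}
    k = model.n_states
    L = len(matrix.seqs[0])
    total = 0.0
    for site in range(L):
        site_lik = 0.0
        for rate in rates:
            P = {n: model.transition_matrix((n.edge.length or 0.0) * rate)
                 for n in nodes if n.parent_node is not None}
            for assignment in itertools.product(range(k), repeat=len(internal)):
                state = dict(zip(internal, assignment))
                for leaf in leaves:
                    c = seq_of[leaf.taxon.label][site]
                    state[leaf] = state_of.get(c)
                lik = model.frequencies[state[tree.seed_node]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    s = state[n]
                    if s is None:  # missing tip: marginalise
                        lik *= 1.0
                    else:
                        lik *= P[n][state[n.parent_node], s]
                site_lik += lik / len(rates)
        total += np.log(site_lik)
    return total


class TestPruningLikelihood:
    def two_leaf_tree(self, t=0.0):
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(data=f"(a:{t},b:0.0);", schema="newick",
                                 taxon_namespace=ns)
        tree.is_rooted = True
        return tree

    def test_identical_states_zero_branch_gives_log_pi(self):
        model = lg_model()
        aln = FamilyAlignment("f", ["a", "b"], ["A", "A"])
        ll = pruning_loglik(self.two_leaf_tree(), aln, model)
        i = model.states.index("A")
        assert ll == pytest.approx(np.log(model.frequencies[i]), abs=1e-12)

    def test_matches_brute_force_on_small_instances(self):
        """Pruning equals exhaustive state summation on 4-5 leaf trees with
        a reduced 4-state alphabet (keeps enumeration tractable)."""
        from archdc.substmodel import kstate_model
        model = kstate_model(np.array([0.4, 0.3, 0.2, 0.1]), "ACDE", alpha=0.7)
        newicks = [
            "((a:0.1,b:0.25):0.12,(c:0.3,d:0.05):0.2);",
            "(((a:0.1,b:0.2):0.1,c:0.15):0.08,(d:0.3,e:0.1):0.12);",
        ]
        alns = [
            FamilyAlignment("f", ["a", "b", "c", "d"], ["AC", "AD", "C?", "EE"]),
            FamilyAlignment("f", ["a", "b", "c", "d", "e"],
                            ["AC", "A-", "CD", "ED", "EA"]),
        ]
        for newick, aln in zip(newicks, alns):
            tree = dendropy.Tree.get(data=newick, schema="newick")
            tree.is_rooted = True
            fast = pruning_loglik(tree, aln, model)
            slow = brute_force_loglik(tree, aln, model)
            assert fast == pytest.approx(slow, abs=1e-8)

    def test_additive_over_columns(self):
        model = lg_model(alpha=1.0)
        tree = dendropy.Tree.get(data="((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);",
                                 schema="newick")
        tree.is_rooted = True
        aln_ab = FamilyAlignment("f", list("abcd"), ["AC", "CD", "AA", "WY"])
        a1 = FamilyAlignment("f", list("abcd"), ["A", "C", "A", "W"])
        a2 = FamilyAlignment("f", list("abcd"), ["C", "D", "A", "Y"])
        assert pruning_loglik(tree, aln_ab, model) == pytest.approx(
            pruning_loglik(tree, a1, model) + pruning_loglik(tree, a2, model))

    def test_negative_branch_rejected(self):
        tree = dendropy.Tree.get(data="((a:0.1,b:-0.2):0.1,c:0.3);",
                                 schema="newick")
        aln = FamilyAlignment("f", list("abc"), ["A", "C", "D"])
        with pytest.raises(TreeInferError, match="negative"):
            pruning_loglik(tree, aln, lg_model())

    def test_alpha_estimate_tracks_simulation_truth(self):
        """Golden-section alpha estimate lands near the generating shape."""
        spec = seqsim.SpeciesTreeSpec(n_ingroup_taxa=6, seed=13,
                                      edge_length_mean=0.15)
        tree = seqsim.simulate_species_tree(spec)
        fam = seqsim.evolve_alignment(
            tree, seqsim.FamilySpec("f", length=2000, gamma_alpha=0.5),
            rng=np.random.default_rng(13))
        est = estimate_alpha(tree, fam, lg_model())
        assert 0.3 < est < 0.9


class TestOutgroupRooting:
    def test_clean_outgroup(self):
        tree = dendropy.Tree.get(data="((o1:1,o2:1):1,(i1:1,i2:1):1,i3:1);",
                                 schema="newick")
        tree.is_rooted = False
        rooted = root_with_outgroup(tree, {"o1", "o2"})
        kids = rooted.seed_node.child_nodes()
        sides = {frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids}
        assert frozenset({"o1", "o2"}) in sides

    def test_single_taxon_outgroup_always_valid(self):
        tree = dendropy.Tree.get(data="(o1:1,(i1:1,i2:1):1,i3:1);",
                                 schema="newick")
        tree.is_rooted = False
        rooted = root_with_outgroup(tree, {"o1"})
        sides = {frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in rooted.seed_node.child_nodes()}
        assert frozenset({"o1"}) in sides

    def test_interleaved_outgroup_rejected(self):
        tree = dendropy.Tree.get(data="((o1:1,i1:1):1,(o2:1,i2:1):1,i3:1);",
                                 schema="newick")
        tree.is_rooted = False
        with pytest.raises(TreeInferError, match="not monophyletic"):
            root_with_outgroup(tree, {"o1", "o2"})

    def test_missing_outgroup_taxa_rejected(self):
        tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
        with pytest.raises(TreeInferError, match="not in tree"):
            root_with_outgroup(tree, {"zz"})
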