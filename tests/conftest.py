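"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from archdc import seqsim
from archdc.io_phylo import METADATA_COLUMNS, FamilyAlignment
from archdc.substmodel import lg_model


@pytest.fixture(scope="session")
def lg():
    return lg_model()


@pytest.fixture(scope="session")
def small_dataset():
    """12 archaea (2 fast 'nano' taxa), 4 bacteria, 4 eukaryotes, 8 families
    (one carrying an HGT event), one duplicated strain."""
    spec = seqsim.DatasetSpec(
        n_archaea=12, n_bacteria=4, n_eucarya=4, fast_clade_size=2,
        n_strain_duplicates=1, seed=11,
        families=seqsim.default_family_specs(n_complex=1),
    )
    return seqsim.simulate_dataset(spec)


def toy_metadata(rows):
    """rows: iterable of (taxon_id, domain, order, species, strain)."""
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def make_alignment(family_id, seq_of, presence_class=None):
    ids = list(seq_of)
    return FamilyAlignment(family_id, ids, [seq_of[i] for i in ids], presence_class)


# ---------------------------------------------------------------------------
# Tree enumeration oracles


def all_unrooted_topologies(labels):
    """Every unrooted binary topology over ``labels`` as nested-tuple trees.

    Built by recursive edge insertion: 1, 1, 3, 15, 105, 945, 10395 ... trees
    for 3, 4, 5, 6, 7, 8 leaves.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def insert_everywhere(tree, leaf):
        # tree is a 3-tuple at the top (unrooted anchor); subtrees are
        # 2-tuples or labels
        def insert_sub(sub):
            out = []
            if isinstance(sub, tuple):
                for i, child in enumerate(sub):
                    for new_child in insert_sub(child):
                        out.append(tuple(new_child if j == i else c
                                         for j, c in enumerate(sub)))
            out.append((sub, leaf))
            return out

        results = []
        for i, child in enumerate(tree):
            for new_child in insert_sub(child):
                results.append(tuple(new_child if j == i else c
                                     for j, c in enumerate(tree)))
        return results

    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        trees = [t for tree in trees for t in insert_everywhere(tree, leaf)]
    return trees


def topology_to_newick(tree) -> str:
    def fmt(sub):
        if isinstance(sub, tuple):
            return "(" + ",".join(fmt(c) for c in sub) + ")"
        return str(sub)

    return fmt(tree) + ";"


def topology_bipartitions(tree):
    """Non-trivial bipartitions of a nested-tuple unrooted topology."""
    leaves = set()

    def collect(sub):
        if isinstance(sub, tuple):
            s = frozenset()
            for c in sub:
                s |= collect(c)
            return s
        leaves.add(sub)
        return frozenset([sub])

    all_leaves = collect(tree)
    bips = set()

    def walk(sub):
        if not isinstance(sub, tuple):
            return frozenset([sub])
        below = frozenset()
        for c in sub:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            bips.add(frozenset({below, all_leaves - below}))
        return below

    for c in tree:
        walk(c)
    return bips


def fitch_length(tree, state_of) -> int:
    """Fitch parsimony length of one character on a nested-tuple topology.

    The ternary anchor is rooted as (a, (b, c)) first, so every internal
    node is binary and the classic intersection/union recursion applies;
    parsimony length is rooting-invariant.
    """
    if len(tree) == 3:
        tree = (tree[0], (tree[1], tree[2]))
    changes = 0

    def fitch(sub):
        nonlocal changes
        if not isinstance(sub, tuple):
            return {state_of[sub]}
        a, b = fitch(sub[0]), fitch(sub[1])
        if a & b:
            return a & b
        changes += 1
        return a | b

    fitch(tree)
    return changes


def newick_to_dendropy(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree
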