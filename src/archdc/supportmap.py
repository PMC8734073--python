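"""Cross-analysis branch-support integration.

Trees inferred from different supermatrices carry different taxon sets, so
branches are compared as bipartitions restricted to shared taxa.  A
reference branch is *supported* by an analysis when the restricted
bipartition occurs in that analysis' tree, and *conflicting* when it does
not, with conflict support taken as the maximum support among incompatible
bipartitions (two bipartitions over one universe are incompatible iff all
four pairwise block intersections are non-empty).  Calls are coloured on the
usual four-way scheme: green (supported, above threshold), light green
(supported, below), light red (conflicting, below), red (conflicting,
above); branches with too few shared taxa are reported absent.

The module also houses the maxdiff convergence statistic between tree
samples and the divide-and-conquer root-transfer step that places the
outgroup-derived root onto a richer unrooted topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

CATEGORIES = ("green", "light_green", "light_red", "red", "absent")
MIN_SHARED_TAXA = 4


class SupportMapError(ValueError):
    pass


@dataclass(frozen=True)
class Bipartition:
    """Unordered pair of disjoint non-empty leaf-label blocks."""

    blocks: frozenset  # frozenset of two frozensets

    @classmethod
    def from_blocks(cls, a, b) -> "Bipartition":
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise SupportMapError("bipartition blocks must be non-empty")
        if a & b:
            raise SupportMapError(f"blocks overlap: {sorted(a & b)}")
        return cls(frozenset({a, b}))

    @property
    def universe(self) -> frozenset:
        a, b = self.blocks_pair()
        return a | b

    def blocks_pair(self):
        pair = sorted(self.blocks, key=lambda s: (len(s), tuple(sorted(s))))
        if len(pair) == 1:  # both blocks identical is impossible (disjoint)
            raise SupportMapError("degenerate bipartition")
        return pair[0], pair[1]

    def smaller_block(self) -> frozenset:
        return self.blocks_pair()[0]

    def is_trivial(self) -> bool:
        return min(len(b) for b in self.blocks) <= 1

    def restrict(self, shared) -> "Bipartition | None":
        """Drop labels outside ``shared``; None if a block empties."""
        shared = frozenset(shared)
        a, b = self.blocks_pair()
        a, b = a & shared, b & shared
        if not a or not b:
            return None
        return Bipartition.from_blocks(a, b)

    def compatible_with(self, other: "Bipartition") -> bool:
        """Co-displayable on one tree: some pairwise block intersection empty."""
        a1, a2 = self.blocks_pair()
        b1, b2 = other.blocks_pair()
        return not (a1 & b1 and a1 & b2 and a2 & b1 and a2 & b2)

    def branch_id(self) -> str:
        return "|".join(sorted(self.smaller_block()))


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> dict:
    """Map each internal branch's bipartition to its support (or None).

    For an unrooted binary tree of n leaves this yields n - 3 entries.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        above = leaves - below
        if not above:
            continue  # child of the root spanning everything (rooted trees)
        bip = Bipartition.from_blocks(below, above)
        if bip.is_trivial() and not include_trivial:
            continue
        support = getattr(node, "support", None)
        if bip in out:
            prev = out[bip]
            support = max(s for s in (prev, support) if s is not None) \
                if (prev is not None or support is not None) else None
        out[bip] = support
    return out


def annotate_supports(tree: dendropy.Tree, support_of: dict) -> None:
    """Write supports (keyed by Bipartition) back onto matching branches."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if not hasattr(node, "support"):
            node.support = None
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        above = leaves - below
        if not above:
            continue
        bip = Bipartition.from_blocks(below, above)
        if bip in support_of:
            node.support = support_of[bip]


@dataclass
class BranchCall:
    branch_id: str
    analysis_id: str
    status: str  # supported | conflicting | unresolved
    support: float | None
    category: str


def _categorize(status: str, support: float | None, threshold: float) -> str:
    if status == "unresolved":
        return "absent"
    value = support if support is not None else 0.0
    if status == "supported":
        return "green" if value >= threshold else "light_green"
    return "red" if value >= threshold else "light_red"


def classify_branch(ref_bip: Bipartition, test_tree: dendropy.Tree,
                    pp_threshold: float = 0.95, bv_threshold: float = 0.95,
                    support_kind: str = "pp",
                    analysis_id: str = "") -> BranchCall:
    """Call one reference branch against one analysis tree.

    Both the reference bipartition and the test tree's bipartitions are
    restricted to the taxa the two analyses share before comparison.
    """
    for th in (pp_threshold, bv_threshold):
        if not 0 < th <= 1:
            raise SupportMapError(f"threshold {th} outside (0, 1]")
    threshold = pp_threshold if support_kind == "pp" else bv_threshold

    test_leaves = frozenset(l.taxon.label for l in test_tree.leaf_node_iter())
    shared = ref_bip.universe & test_leaves
    restricted = ref_bip.restrict(shared) if len(shared) >= MIN_SHARED_TAXA else None
    if restricted is None or restricted.is_trivial():
        return BranchCall(ref_bip.branch_id(), analysis_id, "unresolved", None,
                          "absent")

    found = False
    matched_support = None
    conflict_support = None
    for bip, support in bipartitions(test_tree).items():
        r = bip.restrict(shared)
        if r is None or r.is_trivial():
            continue
        if r == restricted:
            found = True
            if support is not None and (matched_support is None
                                        or support > matched_support):
                matched_support = support
        elif not r.compatible_with(restricted):
            s = support if support is not None else 0.0
            if conflict_support is None or s > conflict_support:
                conflict_support = s

    if found:
        status, value = "supported", matched_support
    else:
        status, value = "conflicting", conflict_support
    category = _categorize(status, value, threshold)
    return BranchCall(ref_bip.branch_id(), analysis_id, status, value, category)


@dataclass
class SupportTable:
    """Per-reference-branch calls across analyses (the dot-grid table)."""

    branch_ids: list
    analysis_ids: list
    calls: dict = field(default_factory=dict)  # (branch_id, analysis_id) -> BranchCall

    def categories(self) -> pd.DataFrame:
        data = {
            an: [self.calls[(b, an)].category for b in self.branch_ids]
            for an in self.analysis_ids
        }
        return pd.DataFrame(data, index=self.branch_ids)

    def supports(self) -> pd.DataFrame:
        data = {
            an: [self.calls[(b, an)].support for b in self.branch_ids]
            for an in self.analysis_ids
        }
        return pd.DataFrame(data, index=self.branch_ids)

    def to_tsv(self, path) -> None:
        rows = []
        for (b, an), call in sorted(self.calls.items()):
            rows.append({
                "branch": b, "analysis": an, "status": call.status,
                "support": call.support, "category": call.category,
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def support_grid(reference_tree: dendropy.Tree, analyses: list) -> SupportTable:
    """Classify every internal reference branch against every analysis.

    ``analyses`` is a list of ``(analysis_id, tree, support_kind)`` with
    ``support_kind`` in {"pp", "bv"}.
    """
    ref_bips = list(bipartitions(reference_tree))
    branch_ids = [b.branch_id() for b in ref_bips]
    table = SupportTable(branch_ids, [a[0] for a in analyses])
    for an_id, tree, kind in analyses:
        for bip in ref_bips:
            call = classify_branch(bip, tree, support_kind=kind, analysis_id=an_id)
            table.calls[(bip.branch_id(), an_id)] = call
    return table


def plot_grid(table: SupportTable, path) -> None:
    """Dot-grid rendering of a SupportTable (rows: branches, cols: analyses)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"green": "#1a9641", "light_green": "#a6d96a",
              "light_red": "#fdae61", "red": "#d7191c", "absent": "#cccccc"}
    cats = table.categories()
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * len(table.analysis_ids), 1 + 0.3 * len(table.branch_ids))
    )
    for y, b in enumerate(cats.index):
        for x, an in enumerate(cats.columns):
            ax.scatter(x, y, s=120, color=colors[cats.loc[b, an]],
                       edgecolors="black", linewidths=0.4)
    ax.set_xticks(range(len(cats.columns)), cats.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(cats.index)),
                  [b[:40] for b in cats.index], fontsize=6)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Convergence diagnostic


def _sample_frequencies(trees: list) -> dict:
    freq = {}
    for tree in trees:
        for bip in bipartitions(tree):
            freq[bip] = freq.get(bip, 0) + 1
    return {bip: cnt / len(trees) for bip, cnt in freq.items()}


def maxdiff(sample_1: list, sample_2: list) -> float:
    """Largest bipartition-frequency gap between two tree samples.

    The classic MCMC convergence check: values below 0.3 indicate the two
    runs sample compatible posteriors.
    """
    if not sample_1 or not sample_2:
        raise SupportMapError("tree samples must be non-empty")
    u1 = frozenset(l.taxon.label for l in sample_1[0].leaf_node_iter())
    for tree in list(sample_1) + list(sample_2):
        u = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        if u != u1:
            raise SupportMapError("tree samples must share one taxon universe")
    f1 = _sample_frequencies(sample_1)
    f2 = _sample_frequencies(sample_2)
    diffs = [abs(f1.get(b, 0.0) - f2.get(b, 0.0)) for b in set(f1) | set(f2)]
    return max(diffs, default=0.0)


# ---------------------------------------------------------------------------
# Root transfer


def root_bipartition(rooted_tree: dendropy.Tree) -> Bipartition:
    children = rooted_tree.seed_node.child_nodes()
    if len(children) != 2:
        raise SupportMapError("reference tree root must be bifurcating")
    a = frozenset(l.taxon.label for l in children[0].leaf_iter())
    b = frozenset(l.taxon.label for l in children[1].leaf_iter())
    return Bipartition.from_blocks(a, b)


def transfer_root(unrooted_tree: dendropy.Tree,
                  rooted_reference: dendropy.Tree) -> dendropy.Tree:
    """Place the reference's root on the matching branch of a richer tree.

    The reference root bipartition, restricted to the taxa shared with the
    unrooted tree, must occur there exactly; otherwise the transfer fails
    loudly (naming the nearest compatible branches) rather than guessing.
    """
    ref_bip = root_bipartition(rooted_reference)
    leaves = frozenset(l.taxon.label for l in unrooted_tree.leaf_node_iter())
    shared = ref_bip.universe & leaves
    restricted = ref_bip.restrict(shared)
    if restricted is None:
        raise SupportMapError(
            "reference root bipartition is degenerate on the shared taxa"
        )

    target = None
    closest, closest_score = None, -1.0
    work = unrooted_tree.clone(depth=1)
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        bip_r = Bipartition.from_blocks(below, leaves - below).restrict(shared) \
            if below and leaves - below else None
        if bip_r is None:
            continue
        if bip_r == restricted:
            target = node
            break
        if bip_r.compatible_with(restricted):
            a, _ = restricted.blocks_pair()
            score = max(len(a & blk) / len(a | blk) for blk in bip_r.blocks_pair())
            if score > closest_score:
                closest, closest_score = bip_r, score
    if target is None:
        hint = closest.branch_id() if closest is not None else "none"
        raise SupportMapError(
            "root bipartition "
            f"{restricted.branch_id()} absent from the unrooted tree; "
            f"closest compatible branch: {hint}"
        )
    length = target.edge.length or 0.0
    work.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    work.is_rooted = True
    for node in work.preorder_node_iter():
        if not hasattr(node, "support"):
            node.support = None
    return work
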