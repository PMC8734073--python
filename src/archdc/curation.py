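"""Marker-family screening and taxon subsampling.

Families whose gene trees break the monophyly of known taxonomic groups
(orders, classes) more often than a tolerance are flagged as "complex" —
the reproducible stand-in for eyeballing gene trees for horizontal transfer,
duplication and loss — and excluded from supermatrix construction.  Taxon
subsampling keeps one strain per species and a fixed number of species per
archaeal order, ranked by data completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .io_phylo import FamilyAlignment

DOMAINS = ("Archaea", "Bacteria", "Eucarya")


class CurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Monophyly screening


def _edge_leafsets(tree: dendropy.Tree):
    """Leaf-label set under each edge (postorder); covers every bipartition."""
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for child in node.child_nodes():
                s |= below[child]
            below[node] = s
    return below


def check_group_monophyly(gene_tree: dendropy.Tree, groups: dict,
                          universe=None) -> list[str]:
    """Names of groups not monophyletic in ``gene_tree``.

    A group is violated iff no branch of the tree induces a bipartition
    separating exactly the group's members present in the tree from all other
    leaves.  Groups with fewer than two present members are skipped.  If
    ``universe`` is given, group members must come from it (absent-from-tree
    members are then legal and ignored); otherwise every member must be a
    leaf of the tree.
    """
    leaves = frozenset(l.taxon.label for l in gene_tree.leaf_node_iter())
    known = frozenset(universe) if universe is not None else leaves
    below = _edge_leafsets(gene_tree)
    leafsets = set(below.values())
    violated = []
    for name in sorted(groups):
        members = frozenset(groups[name])
        unknown = members - known
        if unknown:
            raise CurationError(
                f"group {name!r} references unknown taxa: {sorted(unknown)}"
            )
        present = members & leaves
        if len(present) < 2:
            continue
        complement = leaves - present
        # a clade on either side of some branch realises the bipartition
        if present not in leafsets and complement not in leafsets:
            violated.append(name)
    return violated


@dataclass
class FamilyAssessment:
    family_id: str
    presence_class: str | None
    violated_groups: list = field(default_factory=list)
    flagged: bool = False


def assess_family(fam: FamilyAlignment, gene_tree: dendropy.Tree,
                  groups: dict, universe=None) -> FamilyAssessment:
    violated = check_group_monophyly(gene_tree, groups, universe=universe)
    return FamilyAssessment(fam.family_id, fam.presence_class, violated)


def flag_complex_families(assessments: list, tolerance: int = 0):
    """Split families into retained and flagged by violation count.

    Returns ``(retained_ids, report)`` where the report is a DataFrame with
    one row per family.  A family is flagged iff it violates more than
    ``tolerance`` groups (default 0: any violation flags).
    """
    if not assessments:
        raise CurationError("no families to assess")
    if tolerance < 0:
        raise CurationError("tolerance must be >= 0")
    rows = []
    retained = []
    for a in assessments:
        a.flagged = len(a.violated_groups) > tolerance
        if not a.flagged:
            retained.append(a.family_id)
        rows.append({
            "family_id": a.family_id,
            "presence_class": a.presence_class,
            "n_violations": len(a.violated_groups),
            "violated_groups": ",".join(a.violated_groups),
            "flagged": a.flagged,
        })
    report = pd.DataFrame(rows)
    return retained, report


# ---------------------------------------------------------------------------
# Presence classes


def classify_family_presence(fam: FamilyAlignment, metadata: pd.DataFrame) -> str:
    """Presence class from the domains represented among the family's taxa.

    One sequence of a domain counts as presence.  Every marker must contain
    at least one archaeal sequence (the panel is archaeal-anchored).
    """
    domain_of = dict(zip(metadata["taxon_id"], metadata["domain"]))
    stray = [t for t in fam.ids if t not in domain_of]
    if stray:
        raise CurationError(
            f"family {fam.family_id}: ids missing from metadata: {stray}"
        )
    present = {domain_of[t] for t in fam.ids}
    if "Archaea" not in present:
        raise CurationError(f"family {fam.family_id} has no archaeal sequence")
    has_b, has_e = "Bacteria" in present, "Eucarya" in present
    if has_b and has_e:
        return "universal"
    if has_b:
        return "AB_only"
    if has_e:
        return "AE_only"
    return "A_only"


# ---------------------------------------------------------------------------
# Taxon subsampling


def completeness(metadata: pd.DataFrame, families: list | None) -> pd.Series:
    """Fraction of families containing each taxon (1.0 when no families given)."""
    taxa = metadata["taxon_id"]
    if not families:
        return pd.Series(1.0, index=taxa.values)
    counts = pd.Series(0, index=taxa.values, dtype=float)
    for fam in families:
        counts.loc[counts.index.intersection(fam.ids)] += 1
    return counts / len(families)


def subsample_taxa(metadata: pd.DataFrame, families: list | None = None,
                   min_per_order: int = 3,
                   one_strain_per_species: bool = True) -> set:
    """Representative taxon set: one strain per species, then per archaeal
    order the ``min_per_order`` most complete species (all of them when the
    order has fewer).  Non-archaeal taxa pass through the strain rule only.
    Completeness ties break lexicographically by taxon id, so the result is
    deterministic and idempotent.
    """
    md = metadata.copy()
    score = completeness(metadata, families)
    md["_score"] = md["taxon_id"].map(score)
    md = md.sort_values(["_score", "taxon_id"], ascending=[False, True],
                        kind="stable")
    if one_strain_per_species:
        md = md.drop_duplicates(subset=["domain", "order", "species"], keep="first")

    kept = set(md.loc[md["domain"] != "Archaea", "taxon_id"])
    for _, block in md[md["domain"] == "Archaea"].groupby("order", sort=False):
        kept |= set(block["taxon_id"].head(min_per_order))
    return kept
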