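"""Synthetic dataset generation: species trees, evolved alignments, HGT.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted species tree with two deep ingroup clades ("cluster I" /
"cluster II") plus a distant outgroup; a fast-evolving nanosized clade whose
branches are scaled by a rate multiplier; marker families whose taxonomic
presence falls in four classes (universal, archaea+bacteria, archaea+eucarya,
archaea-only); LG substitutions with four discrete gamma rate categories; and
occasional horizontal transfers that break a group's monophyly in the gene
tree.

All randomness flows from a single master seed; per-family streams are
derived deterministically so datasets are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io_phylo
from .io_phylo import FamilyAlignment
from .substmodel import SubstitutionModel, discrete_gamma_rates, lg_model

PRESENCE_CLASSES = ("universal", "AB_only", "AE_only", "A_only")

#: domains carrying sequences for each presence class
CLASS_DOMAINS = {
    "universal": {"Archaea", "Bacteria", "Eucarya"},
    "AB_only": {"Archaea", "Bacteria"},
    "AE_only": {"Archaea", "Eucarya"},
    "A_only": {"Archaea"},
}


class InvalidSpecError(ValueError):
    pass


@dataclass
class SpeciesTreeSpec:
    """Shape of the simulated species tree.

    The ingroup is split into two clusters joined at the ingroup root by stems
    of ``cluster_split_depth / 2`` each; the outgroup attaches below with its
    own stem.  ``fast_clade_taxa`` names leaves whose spanned subtree gets all
    branch lengths multiplied by ``fast_clade_rate_multiplier``.
    """

    n_ingroup_taxa: int
    n_outgroup_taxa: int = 0
    cluster_split_depth: float = 0.3
    fast_clade_taxa: tuple = ()
    fast_clade_rate_multiplier: float = 1.0
    seed: int = 0
    edge_length_mean: float = 0.05
    min_edge_length: float = 0.01
    outgroup_stem_length: float = 0.8
    cluster_sizes: tuple | None = None  # (n1, n2); default even split
    ingroup_prefix: str = "I"
    outgroup_prefix: str = "O"

    def __post_init__(self):
        if self.n_ingroup_taxa < 4:
            raise InvalidSpecError("need at least 4 ingroup taxa")
        if self.fast_clade_rate_multiplier < 1:
            raise InvalidSpecError("fast-clade rate multiplier must be >= 1")
        if self.cluster_split_depth <= 0:
            raise InvalidSpecError("cluster split depth must be positive")
        if self.cluster_sizes is None:
            n1 = self.n_ingroup_taxa // 2
            self.cluster_sizes = (n1, self.n_ingroup_taxa - n1)
        if min(self.cluster_sizes) < 2:
            raise InvalidSpecError("each cluster needs at least 2 taxa")
        if sum(self.cluster_sizes) != self.n_ingroup_taxa:
            raise InvalidSpecError("cluster sizes must sum to n_ingroup_taxa")

    def ingroup_ids(self) -> list[str]:
        w = len(str(self.n_ingroup_taxa))
        return [f"{self.ingroup_prefix}{i:0{w}d}" for i in range(1, self.n_ingroup_taxa + 1)]

    def outgroup_ids(self) -> list[str]:
        w = max(1, len(str(self.n_outgroup_taxa)))
        return [f"{self.outgroup_prefix}{i:0{w}d}" for i in range(1, self.n_outgroup_taxa + 1)]


def _edge_length(rng: np.random.Generator, mean: float, floor: float) -> float:
    """Edge draw: floor + Exp(mean).  The floor keeps every internal branch
    long enough that the generating topology stays identifiable."""
    return float(floor + rng.exponential(mean))


def _agglomerate(nodes: list, rng: np.random.Generator,
                 mean_length: float, floor: float = 0.0) -> dendropy.Node:
    """Join nodes pairwise in uniform random order; new edges ~ floor + Exp(mean)."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = _edge_length(rng, mean_length, floor)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _random_subtree(taxa: list[str], rng: np.random.Generator,
                    mean_length: float, namespace,
                    floor: float = 0.0) -> dendropy.Node:
    """Random binary subtree over ``taxa`` by uniform agglomeration."""
    leaves = []
    for label in taxa:
        node = dendropy.Node()
        node.taxon = namespace.require_taxon(label)
        node.edge.length = _edge_length(rng, mean_length, floor)
        leaves.append(node)
    return _agglomerate(leaves, rng, mean_length, floor)


def _split_blocks(ids: list[str], n_blocks: int, min_size: int = 2) -> list[list[str]]:
    """Near-equal contiguous blocks, each of at least ``min_size`` ids."""
    n_blocks = max(1, min(n_blocks, len(ids) // min_size))
    base, extra = divmod(len(ids), n_blocks)
    blocks, pos = [], 0
    for b in range(n_blocks):
        size = base + (1 if b < extra else 0)
        blocks.append(ids[pos:pos + size])
        pos += size
    return blocks


def _scale_clade(tree: dendropy.Tree, taxa: set[str], factor: float) -> None:
    if not taxa or factor == 1.0:
        return
    mrca = tree.mrca(taxon_labels=sorted(taxa))
    for node in mrca.preorder_iter():
        if node.edge.length is not None:
            node.edge.length *= factor


def simulate_species_tree(spec: SpeciesTreeSpec) -> dendropy.Tree:
    """Rooted binary species tree whose ingroup root splits the two clusters."""
    rng = np.random.default_rng(spec.seed)
    ns = dendropy.TaxonNamespace()
    ingroup = spec.ingroup_ids()
    n1 = spec.cluster_sizes[0]
    cluster1 = _random_subtree(ingroup[:n1], rng, spec.edge_length_mean, ns,
                               spec.min_edge_length)
    cluster2 = _random_subtree(ingroup[n1:], rng, spec.edge_length_mean, ns,
                               spec.min_edge_length)
    cluster1.edge.length = spec.cluster_split_depth / 2.0
    cluster2.edge.length = spec.cluster_split_depth / 2.0
    ingroup_root = dendropy.Node()
    ingroup_root.add_child(cluster1)
    ingroup_root.add_child(cluster2)

    if spec.n_outgroup_taxa > 0:
        out_ids = spec.outgroup_ids()
        if spec.n_outgroup_taxa == 1:
            out = dendropy.Node()
            out.taxon = ns.require_taxon(out_ids[0])
        else:
            out = _random_subtree(out_ids, rng, spec.edge_length_mean, ns,
                                  spec.min_edge_length)
        out.edge.length = spec.outgroup_stem_length
        ingroup_root.edge.length = spec.outgroup_stem_length
        root = dendropy.Node()
        root.add_child(out)
        root.add_child(ingroup_root)
    else:
        root = ingroup_root

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    unknown = set(spec.fast_clade_taxa) - set(ingroup) - set(
        spec.outgroup_ids() if spec.n_outgroup_taxa else []
    )
    if unknown:
        raise InvalidSpecError(f"fast-clade taxa not in tree: {sorted(unknown)}")
    _scale_clade(tree, set(spec.fast_clade_taxa), spec.fast_clade_rate_multiplier)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution


@dataclass
class FamilySpec:
    family_id: str
    presence_class: str = "A_only"
    length: int = 200
    gamma_alpha: float = 1.0
    n_hgt_events: int = 0

    def __post_init__(self):
        if self.length < 10:
            raise InvalidSpecError("family length must be >= 10")
        if self.gamma_alpha <= 0:
            raise InvalidSpecError("gamma alpha must be positive")
        if self.presence_class not in PRESENCE_CLASSES:
            raise InvalidSpecError(f"unknown presence class {self.presence_class}")
        if self.n_hgt_events < 0:
            raise InvalidSpecError("n_hgt_events must be >= 0")


def _sample_transitions(parent_states: np.ndarray, P: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw child states site-wise from the rows of P given parent states."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def evolve_alignment(tree: dendropy.Tree, fam: FamilySpec,
                     model: SubstitutionModel | None = None,
                     rng: np.random.Generator | None = None,
                     site_rates_out: list | None = None) -> FamilyAlignment:
    """Evolve one family along ``tree`` under ``model`` with G4 rate classes.

    Sites are iid: each draws one of four equal-probability discrete gamma
    rate categories (shape ``fam.gamma_alpha``), then evolves down the tree
    from a stationary root draw.  Branch lengths are expected substitutions
    per site at relative rate one.  If ``site_rates_out`` is a list, the
    per-site relative rates are appended to it (ground truth for tests).
    """
    model = model or lg_model()
    rng = rng if rng is not None else np.random.default_rng(0)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")

    L = fam.length
    k = model.n_states
    rates = discrete_gamma_rates(fam.gamma_alpha, model.n_categories)
    site_cat = rng.integers(0, model.n_categories, size=L)
    if site_rates_out is not None:
        site_rates_out.extend(rates[site_cat].tolist())

    root = tree.seed_node
    root_states = _sample_transitions(
        np.zeros(L, dtype=int),
        np.tile(model.frequencies, (k, 1)),
        rng,
    )
    states = {root: root_states}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        child = np.empty(L, dtype=int)
        for c in range(model.n_categories):
            mask = site_cat == c
            if not mask.any():
                continue
            P = model.transition_matrix(t * rates[c])
            child[mask] = _sample_transitions(parent[mask], P, rng)
        states[node] = child

    alphabet = np.array(list(model.states))
    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append("".join(alphabet[states[leaf]]))
    return FamilyAlignment(fam.family_id, ids, seqs)


def inject_hgt(fam: FamilyAlignment, donor_clade, recipient: str,
               seed: int = 0, model: SubstitutionModel | None = None,
               transfer_distance: float = 0.05) -> FamilyAlignment:
    """Replace ``recipient``'s sequence by one re-evolved from a donor.

    The recipient then clusters inside the donor clade in the gene tree and
    breaks its own group's monophyly — the signature the curation screen is
    built to catch.
    """
    donors = sorted(set(donor_clade))
    if not donors:
        raise ValueError("donor clade is empty")
    if recipient in donors:
        raise ValueError(f"recipient {recipient} is inside the donor clade")
    if recipient not in fam.ids:
        raise ValueError(f"recipient {recipient} not in family {fam.family_id}")
    model = model or lg_model()
    rng = np.random.default_rng(seed)
    donor = donors[int(rng.integers(len(donors)))]
    donor_seq = fam.sequence(donor)
    state_of = {c: i for i, c in enumerate(model.states)}
    P = model.transition_matrix(transfer_distance)
    out = []
    for ch in donor_seq:
        if ch in state_of:
            s = _sample_transitions(np.array([state_of[ch]]), P, rng)[0]
            out.append(model.states[s])
        else:
            out.append(ch)  # gap / missing copied as-is
    seqs = list(fam.seqs)
    seqs[fam.ids.index(recipient)] = "".join(out)
    return FamilyAlignment(fam.family_id, list(fam.ids), seqs, fam.presence_class)


# ---------------------------------------------------------------------------
# Full three-domain datasets


@dataclass
class DatasetSpec:
    """A small three-domain world: bacteria as distant outgroup, archaea in
    two deep clusters (a fast 'nano' clade inside cluster II), eucarya nested
    as sister to the tail of cluster I (the Asgard-like position)."""

    n_archaea: int = 12
    n_bacteria: int = 4
    n_eucarya: int = 4
    n_archaeal_orders: int = 4
    fast_clade_size: int = 0
    fast_clade_rate_multiplier: float = 3.0
    cluster_split_depth: float = 0.3
    edge_length_mean: float = 0.05
    min_edge_length: float = 0.01
    outgroup_stem_length: float = 0.8
    eucarya_stem_length: float = 0.5
    families: list = field(default_factory=list)
    n_strain_duplicates: int = 0  # species receiving a second strain
    seed: int = 0

    def __post_init__(self):
        if self.n_archaea < 4:
            raise InvalidSpecError("need at least 4 archaea")
        if not self.families:
            self.families = default_family_specs()


def default_family_specs(n_universal: int = 3, n_ab: int = 1, n_ae: int = 2,
                         n_a: int = 2, length: int = 120,
                         gamma_alpha: float = 1.0,
                         n_complex: int = 0) -> list[FamilySpec]:
    """A small family panel mixing the four presence classes; the last
    ``n_complex`` families carry one HGT event each."""
    specs = []
    counts = [("universal", n_universal), ("AB_only", n_ab),
              ("AE_only", n_ae), ("A_only", n_a)]
    for cls, n in counts:
        for i in range(1, n + 1):
            specs.append(FamilySpec(f"{cls.lower()}_{i:02d}", cls, length, gamma_alpha))
    for spec, _ in zip(reversed(specs), range(n_complex)):
        spec.n_hgt_events = 1
    return specs


@dataclass
class SimulatedDataset:
    true_tree: dendropy.Tree
    families: list
    taxon_metadata: pd.DataFrame

    def __post_init__(self):
        known = set(self.taxon_metadata["taxon_id"])
        for fam in self.families:
            stray = set(fam.ids) - known
            if stray:
                raise InvalidSpecError(
                    f"family {fam.family_id} has ids missing from metadata: {sorted(stray)}"
                )


def _archaeal_grouping(spec: DatasetSpec):
    """Split archaeal ids into cluster I / cluster II order blocks plus an
    optional fast 'Nano' order (its own block at the end of cluster II)."""
    ids = [f"A{i:02d}" for i in range(1, spec.n_archaea + 1)]
    fast = ids[spec.n_archaea - spec.fast_clade_size:] if spec.fast_clade_size >= 2 else []
    normal = [t for t in ids if t not in set(fast)]
    n1 = len(normal) // 2
    cluster1, cluster2 = normal[:n1], normal[n1:]
    n_orders = max(2, spec.n_archaeal_orders - (1 if fast else 0))
    n_ord1 = max(1, round(n_orders * len(cluster1) / len(normal)))
    n_ord2 = max(1, n_orders - n_ord1)
    blocks1 = _split_blocks(cluster1, n_ord1)
    blocks2 = _split_blocks(cluster2, n_ord2)
    orders = {}
    k = 0
    for block in blocks1 + blocks2:
        k += 1
        for t in block:
            orders[t] = f"Order_{k:02d}"
    for t in fast:
        orders[t] = "Nano_01"
    return cluster1, cluster2, blocks1, blocks2, fast, orders


def simulate_dataset(spec: DatasetSpec,
                     model: SubstitutionModel | None = None) -> SimulatedDataset:
    """Simulate the species tree, metadata table and all family alignments."""
    model = model or lg_model()
    rng = np.random.default_rng(spec.seed)
    ns = dendropy.TaxonNamespace()

    arch_ids = [f"A{i:02d}" for i in range(1, spec.n_archaea + 1)]
    bact_ids = [f"B{i:02d}" for i in range(1, spec.n_bacteria + 1)]
    euk_ids = [f"E{i:02d}" for i in range(1, spec.n_eucarya + 1)]
    _, _, blocks1, blocks2, fast, orders = _archaeal_grouping(spec)

    # orders are built as subtrees, so they are monophyletic by construction
    def order_forest(blocks):
        roots = []
        for block in blocks:
            node = _random_subtree(block, rng, spec.edge_length_mean, ns,
                                   spec.min_edge_length)
            node.edge.length = float(rng.exponential(2 * spec.edge_length_mean)) \
                + spec.edge_length_mean
            roots.append(node)
        return roots

    cluster2_blocks = blocks2 + ([fast] if fast else [])
    cluster1 = _agglomerate(order_forest(blocks1), rng, spec.edge_length_mean,
                            spec.min_edge_length)
    cluster2 = _agglomerate(order_forest(cluster2_blocks), rng,
                            spec.edge_length_mean, spec.min_edge_length)
    cluster1.edge.length = spec.cluster_split_depth / 2.0
    cluster2.edge.length = spec.cluster_split_depth / 2.0

    ingroup_root = dendropy.Node()
    if spec.n_eucarya > 0:
        # eucarya as sister to cluster I (Asgard-like nesting kept simple)
        euk = _random_subtree(euk_ids, rng, spec.edge_length_mean, ns,
                              spec.min_edge_length)
        euk.edge.length = spec.eucarya_stem_length
        pair = dendropy.Node()
        pair.edge.length = spec.cluster_split_depth / 2.0
        cluster1.edge.length = spec.cluster_split_depth / 2.0
        pair.add_child(cluster1)
        pair.add_child(euk)
        ingroup_root.add_child(pair)
    else:
        ingroup_root.add_child(cluster1)
    ingroup_root.add_child(cluster2)

    if spec.n_bacteria > 0:
        bact = _random_subtree(bact_ids, rng, spec.edge_length_mean, ns,
                               spec.min_edge_length)
        bact.edge.length = spec.outgroup_stem_length
        ingroup_root.edge.length = spec.outgroup_stem_length
        root = dendropy.Node()
        root.add_child(bact)
        root.add_child(ingroup_root)
    else:
        root = ingroup_root

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True

    _scale_clade(tree, set(fast), spec.fast_clade_rate_multiplier)

    rows = []
    for t in arch_ids:
        rows.append((t, "Archaea", orders[t], f"sp_{t}", "st1"))
    for t in bact_ids:
        rows.append((t, "Bacteria", "Bacteria_ord", f"sp_{t}", "st1"))
    for t in euk_ids:
        rows.append((t, "Eucarya", "Eucarya_ord", f"sp_{t}", "st1"))

    # optional second strains: new leaves glued next to their species-mates
    strain_hosts = arch_ids[:spec.n_strain_duplicates]
    for host in strain_hosts:
        twin = f"{host}s2"
        leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == host)
        new = dendropy.Node()
        new.taxon = ns.require_taxon(twin)
        new.edge.length = 0.005
        host_edge = leaf.edge.length
        parent = dendropy.Node()
        grand = leaf.parent_node
        grand.remove_child(leaf)
        parent.add_child(leaf)
        parent.add_child(new)
        parent.edge.length = host_edge / 2.0
        leaf.edge.length = host_edge / 2.0
        grand.add_child(parent)
        rows.append((twin, "Archaea", orders[host], f"sp_{host}", "st2"))
    metadata = pd.DataFrame(rows, columns=io_phylo.METADATA_COLUMNS)

    domain_of = dict(zip(metadata["taxon_id"], metadata["domain"]))
    order_of = dict(zip(metadata["taxon_id"], metadata["order"]))
    families = []
    for i, fspec in enumerate(spec.families):
        fam_rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), 1000 + i])
        )
        present_domains = CLASS_DOMAINS[fspec.presence_class]
        keep = [t for t in metadata["taxon_id"] if domain_of[t] in present_domains]
        sub = tree.extract_tree_with_taxa_labels(keep)
        sub.is_rooted = True
        fam = evolve_alignment(sub, fspec, model=model, rng=fam_rng)
        fam.presence_class = fspec.presence_class
        for h in range(fspec.n_hgt_events):
            arch_present = [t for t in fam.ids if domain_of[t] == "Archaea"]
            by_order = {}
            for t in arch_present:
                by_order.setdefault(order_of[t], []).append(t)
            viable = sorted(o for o, ts in by_order.items() if len(ts) >= 2)
            if len(viable) < 2:
                break
            donor_order = viable[h % len(viable)]
            recip_order = viable[(h + 1) % len(viable)]
            recipient = by_order[recip_order][0]
            fam = inject_hgt(fam, by_order[donor_order], recipient,
                             seed=int(fam_rng.integers(2**31)), model=model)
            fam.presence_class = fspec.presence_class
        families.append(fam)

    return SimulatedDataset(tree, families, metadata)


# ---------------------------------------------------------------------------
# On-disk layout


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write FASTA per family, metadata TSV, true tree, and a checksum manifest."""
    outdir = Path(outdir)
    famdir = outdir / "families"
    famdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for fam in ds.families:
        path = famdir / f"{fam.family_id}.fasta"
        io_phylo.write_fasta(fam, path)
        entries[f"families/{fam.family_id}.fasta"] = {
            "sha256": _sha256(path), "presence_class": fam.presence_class,
        }
    io_phylo.write_metadata(ds.taxon_metadata, outdir / "metadata.tsv")
    io_phylo.write_newick(ds.true_tree, outdir / "true_tree.nwk")
    entries["metadata.tsv"] = {"sha256": _sha256(outdir / "metadata.tsv")}
    entries["true_tree.nwk"] = {"sha256": _sha256(outdir / "true_tree.nwk")}
    manifest = {"n_families": len(ds.families), "files": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_dataset(indir) -> SimulatedDataset:
    """Load a dataset written by :func:`write_dataset`, verifying checksums."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    families = []
    for rel, entry in sorted(manifest["files"].items()):
        path = indir / rel
        if not path.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {path}")
        if _sha256(path) != entry["sha256"]:
            raise ValueError(f"checksum mismatch for {path}")
        if rel.startswith("families/"):
            fam = io_phylo.read_fasta(path)
            fam.presence_class = entry.get("presence_class")
            families.append(fam)
    metadata = io_phylo.read_metadata(indir / "metadata.tsv")
    tree = io_phylo.read_newick(indir / "true_tree.nwk", rooted=True)
    return SimulatedDataset(tree, families, metadata)
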