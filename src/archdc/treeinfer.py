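"""Desk-scale tree inference: ML pairwise distances, neighbor joining,
non-parametric bootstrap, and a fixed-topology pruning likelihood.

This stage deliberately trades the heavy Bayesian/ML machinery used on real
supermatrices for exact, fast, testable components behind a pluggable
callback interface: any engine mapping a matrix to a tree with supports can
be slotted into the pipeline in its place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .substmodel import SubstitutionModel, lg_model

DEFAULT_DISTANCE_CAP = 10.0


class TreeInferError(ValueError):
    pass


class Distance(NamedTuple):
    value: float
    saturated: bool


# ---------------------------------------------------------------------------
# Pairwise maximum-likelihood distances


def _encode_rows(rows: list[str], model: SubstitutionModel) -> np.ndarray:
    """Rows as state indices; -1 marks gaps/missing/foreign characters."""
    lut = np.full(256, -1, dtype=np.int16)
    for i, c in enumerate(model.states):
        lut[ord(c)] = i
    flat = np.frombuffer("".join(rows).encode("latin-1"), dtype=np.uint8)
    return lut[flat].reshape(len(rows), -1)


def _pair_counts_encoded(ea: np.ndarray, eb: np.ndarray, k: int) -> np.ndarray:
    ok = (ea >= 0) & (eb >= 0)
    if not ok.any():
        return np.zeros((k, k))
    return np.bincount(ea[ok] * k + eb[ok], minlength=k * k).reshape(k, k).astype(float)


def _pair_counts(seq_a: str, seq_b: str, model: SubstitutionModel) -> np.ndarray:
    enc = _encode_rows([seq_a, seq_b], model)
    return _pair_counts_encoded(enc[0], enc[1], model.n_states)


def ml_distance(seq_a: str, seq_b: str, model: SubstitutionModel | None = None,
                cap: float = DEFAULT_DISTANCE_CAP) -> Distance:
    """Two-sequence ML distance under the model with discrete-gamma rates.

    Maximises ``sum_{a,b} N[a,b] * log(pi_a * mean_c P_c(a -> b; t))`` over
    the evolutionary distance ``t``; columns with a gap or missing state on
    either side are excluded.  Distances at the cap are flagged saturated.
    """
    if len(seq_a) != len(seq_b):
        raise TreeInferError("sequences differ in length")
    model = model or lg_model()
    return _ml_distance_from_counts(_pair_counts(seq_a, seq_b, model), model, cap)


def _ml_distance_from_counts(counts: np.ndarray, model: SubstitutionModel,
                             cap: float) -> Distance:
    n = counts.sum()
    if n == 0:
        raise TreeInferError("no comparable columns between sequences")
    if counts.trace() == n:
        return Distance(0.0, False)
    rates = model.category_rates()
    log_pi = np.log(model.frequencies)

    def negloglik(t: float) -> float:
        P = np.mean([model.transition_matrix(t * r) for r in rates], axis=0)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(P))
        return -np.where(counts > 0, ll, 0.0).sum()

    res = minimize_scalar(negloglik, bounds=(1e-9, cap), method="bounded",
                          options={"xatol": 1e-10})
    t = float(res.x)
    saturated = t > cap * 0.999
    return Distance(cap if saturated else t, saturated)


def distance_matrix(matrix, model: SubstitutionModel | None = None,
                    cap: float = DEFAULT_DISTANCE_CAP):
    """All pairwise ML distances of an alignment/supermatrix.

    Returns ``(ids, D, saturated_mask)``.
    """
    model = model or lg_model()
    ids, rows = matrix.ids, getattr(matrix, "rows", None) or matrix.seqs
    n = len(ids)
    enc = _encode_rows(rows, model)
    k = model.n_states
    D = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_counts_encoded(enc[i], enc[j], k)
            d = _ml_distance_from_counts(counts, model, cap)
            D[i, j] = D[j, i] = d.value
            sat[i, j] = sat[j, i] = d.saturated
    return ids, D, sat


# ---------------------------------------------------------------------------
# Neighbor joining


def nj(D: np.ndarray, ids: list[str]) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; deterministic first-index tie-break.

    Negative branch length estimates are clamped to zero, the usual NJ
    convention.  The returned tree is unrooted (trifurcating anchor).
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if n < 3:
        raise TreeInferError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise TreeInferError("distance matrix must be symmetric with zero diagonal")
    if np.any(D < 0):
        raise TreeInferError("negative distances")

    ns = dendropy.TaxonNamespace()
    nodes = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = ns.require_taxon(label)
        nodes.append(node)
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # first minimum in row-major order
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        nodes[ai].edge.length = float(li)
        nodes[aj].edge.length = float(lj)
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])

        new_row = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        new_index = D.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_index]

    a, b, c = active
    sub = D[np.ix_(active, active)]
    la = 0.5 * (sub[0, 1] + sub[0, 2] - sub[1, 2])
    lb = 0.5 * (sub[0, 1] + sub[1, 2] - sub[0, 2])
    lc = 0.5 * (sub[0, 2] + sub[1, 2] - sub[0, 1])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = float(max(length, 0.0))
        root.add_child(nodes[idx])

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        node.support = None
    return tree


def nj_tree(matrix, model: SubstitutionModel | None = None) -> dendropy.Tree:
    """Convenience: ML distances + NJ in one call."""
    ids, D, _ = distance_matrix(matrix, model)
    return nj(D, ids)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_columns(rows: list[str], rng: np.random.Generator) -> list[str]:
    L = len(rows[0])
    cols = rng.integers(0, L, size=L)
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), L)
    return [bytes(r).decode() for r in arr[:, cols]]


def bootstrap_support(matrix, model: SubstitutionModel | None = None,
                      n_replicates: int = 100, seed: int = 0,
                      cap: float = DEFAULT_DISTANCE_CAP) -> dendropy.Tree:
    """NJ tree on the full matrix with column-resampling bootstrap supports.

    Support of each internal branch = fraction of replicate trees containing
    its bipartition.  Deterministic given the seed.
    """
    from . import supportmap

    if n_replicates < 1:
        raise TreeInferError("need at least one bootstrap replicate")
    model = model or lg_model()
    ids = list(matrix.ids)
    rows = list(getattr(matrix, "rows", None) or matrix.seqs)
    tree = nj_tree(matrix, model)

    tallies = {bip: 0 for bip in supportmap.bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep_rows = _resample_columns(rows, rng)
        try:
            _, D, _ = distance_matrix(_RowView(ids, rep_rows), model, cap)
            rep = nj(D, ids)
        except TreeInferError:
            continue
        rep_bips = supportmap.bipartitions(rep)
        for bip in tallies:
            if bip in rep_bips:
                tallies[bip] += 1

    support_of = {bip: cnt / n_replicates for bip, cnt in tallies.items()}
    supportmap.annotate_supports(tree, support_of)
    return tree


@dataclass
class _RowView:
    ids: list
    rows: list


# ---------------------------------------------------------------------------
# Pruning likelihood


def _tip_partials(seq: str, model: SubstitutionModel) -> np.ndarray:
    state_of = {c: i for i, c in enumerate(model.states)}
    k = model.n_states
    out = np.zeros((len(seq), k))
    for j, c in enumerate(seq):
        i = state_of.get(c)
        if i is None:  # missing/gap: likelihood one for every state
            out[j, :] = 1.0
        else:
            out[j, i] = 1.0
    return out


def pruning_loglik(tree: dendropy.Tree, matrix,
                   model: SubstitutionModel | None = None) -> float:
    """Felsenstein pruning log-likelihood with discrete-gamma categories.

    Missing characters contribute likelihood one at their tips; the root is
    placed at the tree's seed node (valid under reversibility).
    """
    model = model or lg_model()
    ids = list(matrix.ids)
    rows = list(getattr(matrix, "rows", None) or matrix.seqs)
    seq_of = dict(zip(ids, rows))
    leaf_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    stray = set(leaf_labels) - set(ids)
    if stray:
        raise TreeInferError(f"tree leaves missing from matrix: {sorted(stray)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeInferError(f"negative branch length {edge.length}")

    # compress to unique columns
    L = len(rows[0])
    columns = list(zip(*(seq_of[lab] for lab in leaf_labels)))
    patterns = {}
    for col in columns:
        patterns[col] = patterns.get(col, 0) + 1
    pat_list = list(patterns)
    weights = np.array([patterns[p] for p in pat_list], dtype=float)
    pat_seqs = ["".join(p) for p in zip(*pat_list)] if pat_list else []
    pat_of = dict(zip(leaf_labels, pat_seqs))

    rates = model.category_rates()
    n_pat = len(pat_list)
    k = model.n_states
    site_lik = np.zeros(n_pat)
    for rate in rates:
        partial = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partial[node] = _tip_partials(pat_of[node.taxon.label], model)
            else:
                prod = np.ones((n_pat, k))
                for child in node.child_nodes():
                    P = model.transition_matrix((child.edge.length or 0.0) * rate)
                    prod *= partial[child] @ P.T
                partial[node] = prod
        site_lik += (partial[tree.seed_node] @ model.frequencies) / len(rates)
    if np.any(site_lik <= 0):
        return -np.inf
    return float(weights @ np.log(site_lik))


def estimate_alpha(tree: dendropy.Tree, matrix,
                   model: SubstitutionModel | None = None,
                   bounds=(0.05, 20.0)) -> float:
    """Gamma shape maximising the fixed-topology pruning likelihood
    (golden-section/bounded scalar search)."""
    model = model or lg_model()

    def neg(alpha: float) -> float:
        return -pruning_loglik(tree, matrix, model.with_alpha(alpha))

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root on the branch separating a monophyletic outgroup from the rest."""
    from . import supportmap

    outgroup = frozenset(outgroup)
    if not outgroup:
        raise TreeInferError("empty outgroup")
    rooted = tree.clone(depth=1)
    rooted.is_rooted = False
    leaves = frozenset(l.taxon.label for l in rooted.leaf_node_iter())
    stray = outgroup - leaves
    if stray:
        raise TreeInferError(f"outgroup taxa not in tree: {sorted(stray)}")
    if outgroup == leaves:
        raise TreeInferError("outgroup covers every leaf")

    target = None
    for node in rooted.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == outgroup or leaves - below == outgroup:
            target = node
            break
    if target is None:
        bip = supportmap.Bipartition.from_blocks(outgroup, leaves - outgroup)
        raise TreeInferError(
            f"outgroup is not monophyletic: no branch realises {bip.branch_id()}"
        )
    length = target.edge.length or 0.0
    rooted.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                          update_bipartitions=False)
    rooted.is_rooted = True
    for node in rooted.preorder_node_iter():
        if not hasattr(node, "support"):
            node.support = None
    return rooted


# ---------------------------------------------------------------------------
# Optional NNI hill-climb


def _nni_neighbours(tree: dendropy.Tree):
    """Yield trees one nearest-neighbour interchange away (internal edges)."""
    newick = tree.as_string(schema="newick")
    for idx, edge in enumerate(tree.preorder_edge_iter()):
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None or head.parent_node.parent_node is None:
            continue
        for swap in (0, 1):
            clone = dendropy.Tree.get(data=newick, schema="newick",
                                      taxon_namespace=tree.taxon_namespace)
            clone.is_rooted = tree.is_rooted
            c_edge = list(clone.preorder_edge_iter())[idx]
            child = c_edge.head_node.child_nodes()[0]
            parent = c_edge.head_node.parent_node
            siblings = [c for c in parent.child_nodes() if c is not c_edge.head_node]
            if not siblings:
                continue
            sib = siblings[0]
            other = c_edge.head_node.child_nodes()[swap]
            # swap `other` with the sibling across the internal edge
            c_edge.head_node.remove_child(other)
            parent.remove_child(sib)
            c_edge.head_node.add_child(sib)
            parent.add_child(other)
            yield clone


def nni_search(tree: dendropy.Tree, matrix, model: SubstitutionModel | None = None,
               max_rounds: int = 10) -> dendropy.Tree:
    """Greedy NNI hill-climb on the pruning likelihood (branch lengths kept).

    A light topology polisher for the NJ starting tree; accepts the first
    improving interchange per round and stops at a local optimum.
    """
    model = model or lg_model()
    best = tree.clone(depth=1)
    best_ll = pruning_loglik(best, matrix, model)
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbours(best):
            ll = pruning_loglik(cand, matrix, model)
            if ll > best_ll + 1e-9:
                best, best_ll = cand, ll
                improved = True
                break
        if not improved:
            break
    for node in best.preorder_node_iter():
        if not hasattr(node, "support"):
            node.support = None
    return best
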