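"""Slow-Fast per-site rate scoring and progressive desaturation.

Each column's rate score is the number of substitutions it implies within
predefined monophyletic groups, counted on a star tree: for each group, the
number of distinct non-missing states minus one (never negative), summed
over groups.  A score of zero means the column is constant (or absent)
within every group.  Desaturation removes the highest-scoring columns in
steps, producing nested matrices labelled ``S_<percent kept>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_phylo import GAP_CHAR, MISSING_CHAR, Partition
from .supermatrix import Supermatrix

DEFAULT_FRACTIONS = (1.0, 0.9, 0.82, 0.7, 0.6, 0.5)
DEFAULT_GROUP_CAP = 7


class SiteRateError(ValueError):
    pass


@dataclass
class GroupSet:
    """Named, pairwise-disjoint taxon groups used to count substitutions.

    Each group must be a trusted monophyletic unit of 2..cap members;
    taxa not covered by any group simply contribute nothing to the scores.
    """

    groups: dict
    cap: int = DEFAULT_GROUP_CAP

    def __post_init__(self):
        seen = {}
        for name in sorted(self.groups):
            members = set(self.groups[name])
            if not 2 <= len(members) <= self.cap:
                raise SiteRateError(
                    f"group {name!r} has {len(members)} members; need 2..{self.cap}"
                )
            for t in members:
                if t in seen:
                    raise SiteRateError(
                        f"taxon {t} appears in groups {seen[t]!r} and {name!r}"
                    )
                seen[t] = name
            self.groups[name] = members

    @property
    def names(self) -> list[str]:
        return sorted(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class SiteRateProfile:
    """Per-column Slow-Fast scores with the induced removal order."""

    scores: np.ndarray  # integer score per column
    group_names: list

    @property
    def n_columns(self) -> int:
        return len(self.scores)

    def removal_order(self) -> np.ndarray:
        """Column indices from fastest to slowest; ties: higher index first."""
        idx = np.arange(self.n_columns)
        return idx[np.lexsort((-idx, -self.scores))]

    def to_frame(self) -> pd.DataFrame:
        order = self.removal_order()
        rank = np.empty(self.n_columns, dtype=int)
        rank[order] = np.arange(self.n_columns)
        return pd.DataFrame({
            "column": np.arange(1, self.n_columns + 1),
            "score": self.scores,
            "removal_rank": rank,
        })


def load_group_config(path=None, cap: int = DEFAULT_GROUP_CAP) -> GroupSet:
    """Load a YAML group file (name -> member list).

    With no path, loads the packaged 19-group archaeal configuration (group
    names from the desaturation protocol; synthetic placeholder members).
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = (files("archdc") / "configs" / "slowfast_groups_synthetic.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return GroupSet({name: set(members) for name, members in raw.items()}, cap=cap)


_IGNORED = {MISSING_CHAR, GAP_CHAR}


def site_rate(matrix: Supermatrix, groups: GroupSet) -> SiteRateProfile:
    """Score every column: sum over groups of (distinct observed states - 1)."""
    row_of = {t: i for i, t in enumerate(matrix.ids)}
    arr = matrix.to_array()
    member_rows = {}
    for name in groups.names:
        present = [row_of[t] for t in sorted(groups.groups[name]) if t in row_of]
        if len(present) < 2:
            raise SiteRateError(
                f"group {name!r} has fewer than 2 members in the matrix"
            )
        member_rows[name] = np.array(present)

    L = matrix.length
    scores = np.zeros(L, dtype=int)
    for name, rows in member_rows.items():
        block = arr[rows, :]
        for j in range(L):
            states = {c for c in block[:, j] if c not in _IGNORED}
            if len(states) > 1:
                scores[j] += len(states) - 1
    return SiteRateProfile(scores, groups.names)


def step_label(n_kept: int, n_total: int) -> str:
    return f"S_{round(100.0 * n_kept / n_total)}"


def desaturate(matrix: Supermatrix, profile: SiteRateProfile,
               keep_fraction: float) -> Supermatrix:
    """Remove the fastest ``(1 - keep_fraction)`` share of columns.

    Exactly ``ceil((1 - keep_fraction) * L)`` columns go, picked from the
    head of the profile's removal order, so successive steps are nested.
    Partitions are re-derived; emptied partitions are dropped.
    """
    if not 0 < keep_fraction <= 1:
        raise SiteRateError(f"keep_fraction must lie in (0, 1], got {keep_fraction}")
    L = matrix.length
    if profile.n_columns != L:
        raise SiteRateError("profile does not match matrix length")
    # epsilon guards the ceiling against float slop (0.18 * 100 -> 18.000…04)
    n_remove = math.ceil((1.0 - keep_fraction) * L - 1e-9)
    removed = set(profile.removal_order()[:n_remove].tolist())
    keep_mask = np.array([j not in removed for j in range(L)])

    rows = ["".join(np.array(list(r))[keep_mask]) for r in matrix.rows]
    parts, start = [], 1
    for p in matrix.partitions:
        kept = int(keep_mask[p.start - 1:p.end].sum())
        if kept == 0:
            continue
        parts.append(Partition(p.name, start, start + kept - 1))
        start += kept
    label = step_label(L - n_remove, L)
    prov = f"{matrix.provenance}:{label}" if matrix.provenance else label
    out = Supermatrix(list(matrix.ids), rows, parts, prov)
    return out


@dataclass
class SlowFastStep:
    label: str
    keep_fraction: float
    n_positions: int
    matrix: Supermatrix | None
    tree: object | None
    error: str | None = None
    branch_calls: dict = field(default_factory=dict)


def run_series(matrix: Supermatrix, groups: GroupSet, infer,
               fractions=DEFAULT_FRACTIONS,
               reference_tree=None, pp_threshold: float = 0.95,
               support_kind: str = "bv") -> list:
    """Infer a tree per desaturation step; optionally classify reference
    branches at each step (the per-step trace behind a support grid).

    ``infer`` is a callback ``matrix -> tree`` (with supports on nodes).
    ``fractions`` must be strictly decreasing.  Inference failures are
    recorded on the step and the series continues.
    """
    fr = list(fractions)
    if any(b >= a for a, b in zip(fr, fr[1:])):
        raise SiteRateError("fractions must be strictly decreasing")
    from . import supportmap

    profile = site_rate(matrix, groups)
    ref_bips = supportmap.bipartitions(reference_tree) if reference_tree is not None else None
    steps = []
    for f in fr:
        sub = desaturate(matrix, profile, f)
        label = sub.provenance.split(":")[-1]
        step = SlowFastStep(label, f, sub.length, sub, None)
        try:
            step.tree = infer(sub)
        except Exception as exc:  # record and continue the series
            step.error = f"{type(exc).__name__}: {exc}"
            steps.append(step)
            continue
        if ref_bips is not None:
            for bip in ref_bips:
                call = supportmap.classify_branch(
                    bip, step.tree, pp_threshold=pp_threshold,
                    support_kind=support_kind,
                )
                step.branch_calls[bip] = call
        steps.append(step)
    return steps


def series_trace(steps: list) -> pd.DataFrame:
    """Long-format trace: one row per (step, reference branch)."""
    rows = []
    for step in steps:
        for bip, call in step.branch_calls.items():
            rows.append({
                "step": step.label,
                "keep_fraction": step.keep_fraction,
                "n_positions": step.n_positions,
                "branch": bip.branch_id(),
                "status": call.status,
                "support": call.support,
                "category": call.category,
            })
    return pd.DataFrame(rows)
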