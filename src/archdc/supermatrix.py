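"""Supermatrix construction: trimming, concatenation, subsetting, recoding.

The three canonical taxon/marker subsets follow the divide-and-conquer
design: ``A`` (all retained families, archaeal taxa only), ``AE`` (universal
and archaea+eucarya families over archaeal plus eukaryotic taxa) and ``AB``
(universal and archaea+bacteria families over archaeal plus bacterial taxa).
Each subset is re-trimmed on its own taxon sampling before concatenation.

Dayhoff recoding collapses the 20 amino acids into biochemical classes:
four classes with cysteine treated as missing (dayhoff4), or six classes
with cysteine its own state (dayhoff6).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_phylo import (GAP_CHAR, MISSING_CHAR, FamilyAlignment, Partition,
                       validate_partitions, write_fasta, write_partitions)

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_MAX_GAP_FRACTION = 0.4
DEFAULT_MAX_ENTROPY = 0.7 * math.log(20.0)

SUBSET_FAMILY_CLASSES = {
    "A": {"universal", "AB_only", "AE_only", "A_only"},
    "AE": {"universal", "AE_only"},
    "AB": {"universal", "AB_only"},
}
SUBSET_DOMAINS = {
    "A": {"Archaea"},
    "AE": {"Archaea", "Eucarya"},
    "AB": {"Archaea", "Bacteria"},
}


class SupermatrixError(ValueError):
    pass


@dataclass
class Supermatrix:
    """Concatenated character matrix with named 1-based partitions."""

    ids: list[str]
    rows: list[str]
    partitions: list[Partition]
    provenance: str = ""

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise SupermatrixError(f"ragged rows: lengths {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise SupermatrixError("duplicate taxon ids")
        if self.partitions:
            validate_partitions(self.partitions)
            total = sum(p.length for p in self.partitions)
            if (total != self.length
                    or min(p.start for p in self.partitions) != 1
                    or max(p.end for p in self.partitions) != self.length):
                raise SupermatrixError(
                    f"partitions cover {total} columns but matrix has {self.length}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        ).astype("U1")

    def row(self, taxon_id: str) -> str:
        return self.rows[self.ids.index(taxon_id)]

    def extract_partition(self, name: str) -> FamilyAlignment:
        """Re-yield one source family (restricted to this matrix's taxa)."""
        part = next((p for p in self.partitions if p.name == name), None)
        if part is None:
            raise SupermatrixError(f"no partition named {name!r}")
        lo, hi = part.start - 1, part.end
        ids, seqs = [], []
        for taxon, row in zip(self.ids, self.rows):
            block = row[lo:hi]
            if set(block) != {MISSING_CHAR}:
                ids.append(taxon)
                seqs.append(block)
        return FamilyAlignment(name, ids, seqs)

    def write(self, fasta_path, partition_path=None) -> None:
        write_fasta(FamilyAlignment(self.provenance or "supermatrix",
                                    self.ids, self.rows), fasta_path)
        if partition_path is not None:
            write_partitions(self.partitions, partition_path)


# ---------------------------------------------------------------------------
# Trimming


def column_entropy(column: str) -> float:
    """Shannon entropy (nats) over observed residues; gaps/missing ignored."""
    observed = [c for c in column if c not in (GAP_CHAR, MISSING_CHAR)]
    if not observed:
        return 0.0
    counts = np.array(list(Counter(observed).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def trim_alignment(fam: FamilyAlignment,
                   max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
                   max_entropy: float = DEFAULT_MAX_ENTROPY) -> FamilyAlignment:
    """Drop columns that are too gappy or too variable, preserving order.

    A column is kept iff its gap+missing fraction is <= ``max_gap_fraction``
    and its residue entropy is <= ``max_entropy``.  This is a deliberately
    simple, fully specified trimmer (entropy + gap share); any external
    trimmer honouring the same contract can be swapped in upstream.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise SupermatrixError("max_gap_fraction must lie in [0, 1]")
    if fam.n_taxa == 0 or fam.length == 0:
        raise SupermatrixError(f"empty alignment {fam.family_id}")
    n = fam.n_taxa
    keep = []
    for j in range(fam.length):
        col = "".join(s[j] for s in fam.seqs)
        gappy = sum(c in (GAP_CHAR, MISSING_CHAR) for c in col) / n
        keep.append(gappy <= max_gap_fraction and column_entropy(col) <= max_entropy)
    return fam.columns_kept(keep)


# ---------------------------------------------------------------------------
# Concatenation and subsets


def concatenate(families: list, taxa) -> Supermatrix:
    """Concatenate families over a fixed taxon set; absent taxa get '?' blocks."""
    if not families:
        raise SupermatrixError("no families to concatenate")
    taxa = sorted(set(taxa))
    if not taxa:
        raise SupermatrixError("empty taxon set")
    parts, start = [], 1
    chunks = {t: [] for t in taxa}
    for fam in families:
        L = fam.length
        seq_of = dict(zip(fam.ids, fam.seqs))
        filler = MISSING_CHAR * L
        for t in taxa:
            chunks[t].append(seq_of.get(t, filler))
        parts.append(Partition(fam.family_id, start, start + L - 1))
        start += L
    rows = ["".join(chunks[t]) for t in taxa]
    return Supermatrix(taxa, rows, parts)


def build_subset(families: list, metadata: pd.DataFrame, subset: str,
                 taxa: set | None = None,
                 max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
                 max_entropy: float = DEFAULT_MAX_ENTROPY) -> Supermatrix:
    """Build the A / AE / AB supermatrix from classified, untrimmed families.

    Families are filtered by presence class, restricted to the subset's
    domains (optionally intersected with ``taxa``, e.g. a curated sample),
    re-trimmed on that restricted sampling, and concatenated.
    """
    if subset not in SUBSET_FAMILY_CLASSES:
        raise SupermatrixError(f"unknown subset {subset!r}; expected A, AE or AB")
    for fam in families:
        if fam.presence_class is None:
            raise SupermatrixError(f"family {fam.family_id} is unclassified")
    wanted = SUBSET_FAMILY_CLASSES[subset]
    domains = SUBSET_DOMAINS[subset]
    pool = set(metadata.loc[metadata["domain"].isin(domains), "taxon_id"])
    if taxa is not None:
        pool &= set(taxa)
    selected = [f for f in families if f.presence_class in wanted]
    if not selected:
        raise SupermatrixError(f"no families match subset {subset}")
    trimmed = []
    for fam in selected:
        sub = fam.restrict(pool)
        if sub.n_taxa == 0:
            continue
        trimmed.append(trim_alignment(sub, max_gap_fraction, max_entropy))
    matrix = concatenate(trimmed, pool)
    matrix.provenance = subset
    return matrix


# ---------------------------------------------------------------------------
# Recoding


@dataclass(frozen=True)
class RecodingScheme:
    name: str
    mapping: dict  # residue -> single-character state label
    missing: frozenset = frozenset({MISSING_CHAR, GAP_CHAR})

    def states(self) -> str:
        return "".join(sorted(set(self.mapping.values()) - self.missing))

    def recode_char(self, c: str) -> str:
        if c in self.missing:
            return c
        try:
            return self.mapping[c]
        except KeyError:
            raise SupermatrixError(f"residue {c!r} outside alphabet") from None


def _scheme(name: str, groups: list[str], cysteine_missing: bool) -> RecodingScheme:
    mapping = {}
    for label, residues in enumerate(groups, start=1):
        for r in residues:
            mapping[r] = str(label)
    if cysteine_missing:
        mapping["C"] = MISSING_CHAR
    return RecodingScheme(name, mapping)


#: four Dayhoff classes, cysteine treated as missing data
DAYHOFF4 = _scheme("dayhoff4", ["AGPST", "DENQ", "HKR", "FYWILMV"], True)
#: six Dayhoff classes, cysteine its own state
DAYHOFF6 = _scheme("dayhoff6", ["AGPST", "DENQ", "HKR", "FYW", "ILMV", "C"], False)

SCHEMES = {"dayhoff4": DAYHOFF4, "dayhoff6": DAYHOFF6}


def recode_string(seq: str, scheme: RecodingScheme) -> str:
    return "".join(scheme.recode_char(c) for c in seq)


def recode_alignment(fam: FamilyAlignment, scheme: RecodingScheme) -> FamilyAlignment:
    return FamilyAlignment(fam.family_id, list(fam.ids),
                           [recode_string(s, scheme) for s in fam.seqs],
                           fam.presence_class)


def recode(matrix: Supermatrix, scheme: RecodingScheme | str) -> Supermatrix:
    """Recode a supermatrix; dimensions and partitions are unchanged."""
    if isinstance(scheme, str):
        try:
            scheme = SCHEMES[scheme]
        except KeyError:
            raise SupermatrixError(f"unknown recoding scheme {scheme!r}") from None
    rows = [recode_string(r, scheme) for r in matrix.rows]
    name = f"{matrix.provenance}+{scheme.name}" if matrix.provenance else scheme.name
    return Supermatrix(list(matrix.ids), rows, list(matrix.partitions), name)


# ---------------------------------------------------------------------------
# Reporting


def matrix_stats(matrix: Supermatrix) -> dict:
    """Dimensions, per-partition lengths, and missing/gap percentages."""
    total = matrix.n_taxa * matrix.length
    n_missing = sum(r.count(MISSING_CHAR) for r in matrix.rows)
    n_gap = sum(r.count(GAP_CHAR) for r in matrix.rows)
    return {
        "subset": matrix.provenance,
        "n_taxa": matrix.n_taxa,
        "n_positions": matrix.length,
        "n_partitions": len(matrix.partitions),
        "partition_lengths": {p.name: p.length for p in matrix.partitions},
        "pct_missing": 100.0 * n_missing / total if total else 0.0,
        "pct_gap": 100.0 * n_gap / total if total else 0.0,
    }


def stats_table(matrices: list) -> pd.DataFrame:
    rows = []
    for m in matrices:
        s = matrix_stats(m)
        s.pop("partition_lengths")
        rows.append(s)
    return pd.DataFrame(rows)
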