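"""Readers and writers for the formats the pipeline touches.

Alignments travel as :class:`FamilyAlignment` (FASTA on disk), trees as
``dendropy.Tree`` with a float ``support`` attribute on internal nodes
(Newick on disk, supports as internal-node labels), partitions as RAxML-style
``NAME = start-end`` records (1-based inclusive), and taxon metadata as TSV.

Branch supports are normalised to [0, 1] on input: a value greater than one is
interpreted as a percentage and divided by 100, so posterior probabilities
(0.97) and bootstrap percentages (97) share one scale.  The normalisation is
idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

#: characters treated as missing data in amino-acid matrices
MISSING_CHARS = frozenset("?XBZJUO")
GAP_CHAR = "-"
MISSING_CHAR = "?"

METADATA_COLUMNS = ["taxon_id", "domain", "order", "species", "strain"]

SUPPORT_CONVENTIONS = ("internal-node-label", "branch-comment")


class AlignmentError(ValueError):
    pass


@dataclass
class FamilyAlignment:
    """One marker family: equal-length sequences keyed by unique taxon ids."""

    family_id: str
    ids: list[str]
    seqs: list[str]
    presence_class: str | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment '{self.family_id}': lengths {sorted(lengths)}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, taxon_id: str) -> str:
        return self.seqs[self.ids.index(taxon_id)]

    def restrict(self, taxa) -> "FamilyAlignment":
        """Keep only the given taxa (order preserved)."""
        taxa = set(taxa)
        kept = [(i, s) for i, s in zip(self.ids, self.seqs) if i in taxa]
        return FamilyAlignment(
            self.family_id,
            [i for i, _ in kept],
            [s for _, s in kept],
            self.presence_class,
        )

    def columns_kept(self, keep_mask) -> "FamilyAlignment":
        seqs = ["".join(s[j] for j, k in enumerate(keep_mask) if k) for s in self.seqs]
        return FamilyAlignment(self.family_id, list(self.ids), seqs, self.presence_class)


def _normalize_residues(seq: str) -> str:
    out = []
    for c in seq.upper():
        out.append(MISSING_CHAR if c in MISSING_CHARS else c)
    return "".join(out)


def read_fasta(path, family_id: str | None = None,
               aligned: bool = True) -> FamilyAlignment:
    """Read a FASTA file into a :class:`FamilyAlignment`.

    Header token 1 is the taxon id.  Lowercase is normalised to uppercase and
    ambiguity/missing codes (X, B, Z, J, U, O) to '?'.  Duplicate ids and, for
    aligned input, ragged lengths raise :class:`AlignmentError`.
    """
    path = Path(path)
    ids, seqs = [], []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            ids.append(header.split()[0])
            seqs.append(_normalize_residues(seq))
    if not ids:
        raise AlignmentError(f"no sequences in {path}")
    if not aligned and len({len(s) for s in seqs}) > 1:
        raise AlignmentError(f"unaligned input not supported: {path}")
    return FamilyAlignment(family_id or path.stem, ids, seqs)


def write_fasta(alignment: FamilyAlignment, path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for taxon, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_phylip(alignment, path) -> None:
    """Relaxed PHYLIP writer (interop only; no reader)."""
    ids = alignment.ids
    seqs = alignment.seqs if hasattr(alignment, "seqs") else alignment.rows
    with open(Path(path), "w") as fh:
        fh.write(f" {len(ids)} {len(seqs[0])}\n")
        for taxon, seq in zip(ids, seqs):
            fh.write(f"{taxon}  {seq}\n")


# ---------------------------------------------------------------------------
# Trees


def normalize_support(value: float) -> float:
    """Map a support value onto [0, 1]; >1 is read as a percentage."""
    v = float(value)
    if v > 1.0:
        v = v / 100.0
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"support {value} not interpretable on [0,1] or [0,100]")
    return v


def _attach_supports_from_labels(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is not None and node.label.strip():
            try:
                node.support = normalize_support(float(node.label))
                node.label = None
            except ValueError:
                pass  # genuine internal-node name, keep it


def _attach_supports_from_comments(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.parent_node is None:
            continue
        for comment in list(node.comments):
            try:
                node.support = normalize_support(float(comment))
                break
            except ValueError:
                continue


def read_newick(source, support_convention: str = "internal-node-label",
                rooted: bool | None = None) -> dendropy.Tree:
    """Parse one Newick tree; supports end up as ``node.support`` in [0, 1].

    ``source`` may be a path or a Newick string.  ``rooted=None`` keeps the
    file's own rooting statement (default unrooted for plain Newick).
    """
    if support_convention not in SUPPORT_CONVENTIONS:
        raise ValueError(f"unknown support convention: {support_convention}")
    text = source if isinstance(source, str) and source.lstrip().startswith("(") \
        else Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"unparseable Newick ({exc})") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    if support_convention == "internal-node-label":
        _attach_supports_from_labels(tree)
    else:
        _attach_supports_from_comments(tree)
    return tree


def write_newick(tree: dendropy.Tree, path=None, support_digits: int = 4) -> str:
    """Serialise with supports as internal-node labels; returns the string."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf() and node.parent_node is not None:
            node.label = f"{support:.{support_digits}g}"
    text = clone.as_string(schema="newick", suppress_rooting=not tree.is_rooted,
                           unquoted_underscores=True)
    text = text.strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Partitions


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad partition range {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_PARTITION_RE = re.compile(
    r"^\s*(?:[A-Za-z0-9+]+\s*,\s*)?(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def validate_partitions(partitions: list[Partition]) -> None:
    spans = sorted(partitions, key=lambda p: p.start)
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping partitions: {a.name} {a.start}-{a.end} and "
                f"{b.name} {b.start}-{b.end}"
            )


def read_partitions(path) -> list[Partition]:
    """RAxML-style partition file: ``NAME = start-end`` (model prefix allowed)."""
    parts = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise ValueError(f"{path}:{lineno}: unparseable partition line: {line!r}")
        parts.append(Partition(m["name"], int(m["start"]), int(m["end"])))
    validate_partitions(parts)
    return parts


def write_partitions(partitions: list[Partition], path) -> None:
    validate_partitions(partitions)
    with open(Path(path), "w") as fh:
        for p in partitions:
            fh.write(f"{p.name} = {p.start}-{p.end}\n")


# ---------------------------------------------------------------------------
# Taxon metadata


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks columns {missing}")
    if df["taxon_id"].duplicated().any():
        dupes = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValueError(f"duplicate taxon ids in metadata: {dupes}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)
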