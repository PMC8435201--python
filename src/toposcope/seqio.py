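"""Readers/writers for alignments, trees, partition maps, and site-lnL tables.

The domain types here are the shared currency of the pipeline:

* :class:`Alignment` — a taxa-by-columns character matrix over a declared
  alphabet, optionally carrying a :class:`PartitionMap` after concatenation.
* :class:`PhyloTree` — a phylogeny with taxon-labelled leaves and
  non-negative branch lengths, parsed from Newick via DendroPy but stored
  in a lightweight mutable node structure suited to likelihood work.
* :class:`SiteLnLMatrix` — per-site log-likelihoods for a set of candidate
  trees; the substrate of the RELL/AU/BIC testing stage.

Coordinates in partition files are 1-based inclusive (the convention of
common ML programs); internally everything is 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import dendropy
import numpy as np
from Bio import SeqIO

from .alphabets import AMINO_ACID, NUCLEOTIDE, Alphabet
from .errors import AlignmentError, FormatError, PartitionError

PathLike = Union[str, Path]

DEFAULT_BRANCH_LENGTH = 0.1


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Multiple sequence alignment: ordered taxa over equal-length rows."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) array of single characters
    alphabet: Alphabet
    partitions: "PartitionMap | None" = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be a 2-D character matrix")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} sequence rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon labels in alignment")
        if any(not t for t in self.taxa):
            raise FormatError("empty taxon label")
        valid = set(self.alphabet.states) | self.alphabet.ambiguous
        bad = set(np.unique(self.data)) - valid
        if bad:
            raise FormatError(
                f"symbols {sorted(bad)} not in {self.alphabet.name} alphabet"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def state_indices(self) -> np.ndarray:
        """Integer state matrix; gap/missing symbols become -1."""
        lookup = {s: i for i, s in enumerate(self.alphabet.states)}
        out = np.full(self.data.shape, -1, dtype=np.int64)
        for sym, idx in lookup.items():
            out[self.data == sym] = idx
        return out

    def subset_columns(self, start: int, stop: int) -> "Alignment":
        """0-based half-open column slice (drops any partition map)."""
        return Alignment(list(self.taxa), self.data[:, start:stop], self.alphabet)

    @classmethod
    def from_sequences(
        cls,
        records: Sequence[tuple[str, str]],
        alphabet: Alphabet,
    ) -> "Alignment":
        if not records:
            raise FormatError("no sequences")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        taxa = [name for name, _ in records]
        data = np.array([list(seq.upper()) for _, seq in records], dtype="<U1")
        return cls(taxa, data, alphabet)


def read_fasta_alignment(path: PathLike, alphabet: Alphabet = AMINO_ACID) -> Alignment:
    """Read an aligned FASTA file; symbols are upper-cased and validated."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment.from_sequences(records, alphabet)


def write_fasta_alignment(alignment: Alignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for taxon in alignment.taxa:
            fh.write(f">{taxon}\n{alignment.sequence(taxon)}\n")


def read_phylip_alignment(path: PathLike, alphabet: Alphabet = AMINO_ACID) -> Alignment:
    """Read a relaxed (whitespace-delimited, sequential) PHYLIP alignment."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError("PHYLIP header must be 'n_taxa n_sites'")
        try:
            n_taxa, n_sites = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError("non-integer PHYLIP header") from exc
        records: list[tuple[str, str]] = []
        name: str | None = None
        chunks: list[str] = []
        for line in fh:
            if not line.strip():
                continue
            if name is None:
                name, *rest = line.split()
                chunks = ["".join(rest)]
            else:
                chunks.append("".join(line.split()))
            if sum(len(c) for c in chunks) >= n_sites:
                records.append((name, "".join(chunks)))
                name, chunks = None, []
    if len(records) != n_taxa:
        raise FormatError(f"expected {n_taxa} sequences, found {len(records)}")
    aln = Alignment.from_sequences(records, alphabet)
    if aln.n_sites != n_sites:
        raise AlignmentError(f"header says {n_sites} sites, rows have {aln.n_sites}")
    return aln


# ---------------------------------------------------------------------------
# PartitionMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionMap:
    """Ordered locus blocks in 1-based inclusive column coordinates."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev_end = 0
        for name, start, end in self.entries:
            if name in seen:
                raise PartitionError(f"duplicate locus name {name!r}")
            seen.add(name)
            if start > end:
                raise PartitionError(f"{name}: start {start} > end {end}")
            if start != prev_end + 1:
                raise PartitionError(
                    f"{name}: starts at {start}, expected {prev_end + 1} "
                    "(partitions must be contiguous and non-overlapping)"
                )
            prev_end = end

    @property
    def n_sites(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.entries)

    def slices(self) -> list[tuple[str, slice]]:
        """0-based half-open column slices per locus."""
        return [(name, slice(start - 1, end)) for name, start, end in self.entries]


def read_partition_map(path: PathLike, n_sites: int | None = None) -> PartitionMap:
    """Parse 'name = start-end' lines into a validated PartitionMap."""
    entries: list[tuple[str, int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'name = start-end'")
        name, _, coords = line.partition("=")
        try:
            start_s, _, end_s = coords.strip().partition("-")
            entries.append((name.strip(), int(start_s), int(end_s)))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad coordinates {coords.strip()!r}") from exc
    pm = PartitionMap(tuple(entries))
    if n_sites is not None and pm.n_sites != n_sites:
        raise PartitionError(
            f"partitions cover 1..{pm.n_sites} but alignment has {n_sites} sites"
        )
    return pm


def write_partition_map(pm: PartitionMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, start, end in pm:
            fh.write(f"{name} = {start}-{end}\n")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class TreeNode:
    """Mutable node of a phylogeny; ``length`` is the edge to the parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class PhyloTree:
    """A phylogeny with labelled leaves and non-negative branch lengths.

    The tree is stored rooted as read; likelihood code treats it as unrooted
    (time-reversible models make the root placement immaterial).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate leaf labels in tree")
        for node in root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.postorder() if n.is_leaf]

    def nodes(self) -> list[TreeNode]:
        return list(self.root.postorder())

    def n_branches(self) -> int:
        return sum(1 for n in self.root.postorder() if n.parent is not None)

    def branch_lengths(self) -> dict[int, float]:
        return {
            id(n): n.length
            for n in self.root.postorder()
            if n.parent is not None
        }

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def unrooted_splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-looking frozenset side)
        identifying the unrooted topology; two trees are topologically equal
        iff their split sets are equal."""
        all_taxa = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node.is_leaf or node.parent is None:
                continue
            side = frozenset(n.label for n in node.postorder() if n.is_leaf)
            other = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                splits.add(min(side, other, key=lambda s: sorted(s)))
        return frozenset(splits)

    def same_unrooted_topology(self, other: "PhyloTree") -> bool:
        return (
            frozenset(self.leaf_labels()) == frozenset(other.leaf_labels())
            and self.unrooted_splits() == other.unrooted_splits()
        )

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                base = node.label or ""
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    base += node.label
            if node.length is not None and node.parent is not None:
                base += f":{node.length:.10g}"
            return base

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree, default_length: float) -> PhyloTree:
    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        if length is None:
            length = default_length
        node = TreeNode(label, length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # the root has no parent edge
    return PhyloTree(root)


def parse_newick(text: str, default_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """Parse a Newick string; absent branch lengths get ``default_length``."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree, default_length)


def read_newick(path: PathLike, default_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    return parse_newick(Path(path).read_text(), default_length)


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# SiteLnLMatrix
# ---------------------------------------------------------------------------

@dataclass
class SiteLnLMatrix:
    """Candidate trees x sites matrix of per-site natural-log likelihoods."""

    tree_ids: list[str]
    values: np.ndarray  # (n_trees, n_sites), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("site-lnL values must be a 2-D matrix")
        if len(self.tree_ids) != self.values.shape[0]:
            raise FormatError("tree id count does not match row count")
        if len(set(self.tree_ids)) != len(self.tree_ids):
            raise FormatError("duplicate tree ids")
        if np.any(np.isnan(self.values)) or np.any(self.values == np.inf):
            raise FormatError("site lnL values must be finite or -inf")

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        """Per-tree total log-likelihood (row sums)."""
        return self.values.sum(axis=1)

    def row(self, tree_id: str) -> np.ndarray:
        return self.values[self.tree_ids.index(tree_id)]


def read_site_lnl_matrix(path: PathLike) -> SiteLnLMatrix:
    """Read a site-lnL table.

    Two dialects are accepted: the package's own TSV (each row
    ``tree_id <TAB> v1 <TAB> v2 ...``) and the per-site lnL output dialect
    of common ML programs (header line ``n_trees n_sites`` followed by
    whitespace-separated ``tree_id v1 v2 ...`` rows).
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty site-lnL file {path}")
    header = lines[0].split()
    start = 0
    if len(header) == 2:
        try:
            int(header[0]), int(header[1])
            start = 1
        except ValueError:
            pass
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: need a tree id and at least one value")
        ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric site lnL") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged site-lnL rows: widths {sorted(widths)}")
    return SiteLnLMatrix(ids, np.array(rows))


def write_site_lnl_matrix(matrix: SiteLnLMatrix, path: PathLike) -> None:
    """Write the package TSV dialect with full float precision (round-trip safe)."""
    with open(path, "w") as fh:
        for tree_id, row in zip(matrix.tree_ids, matrix.values):
            fh.write(tree_id + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


__all__ = [
    "Alignment",
    "PartitionMap",
    "PhyloTree",
    "TreeNode",
    "SiteLnLMatrix",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_phylip_alignment",
    "read_partition_map",
    "write_partition_map",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_site_lnl_matrix",
    "write_site_lnl_matrix",
    "DEFAULT_BRANCH_LENGTH",
    "AMINO_ACID",
    "NUCLEOTIDE",
]
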