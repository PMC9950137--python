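"""Readers, writers and containers for alignments, trees and annotation tables.

All user-facing coordinates are 1-based: alignment columns 1..n_sites and
ungapped residue positions 1..L, matching the residue nomenclature used for
enzyme variants (e.g. "I60", "H275").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
_ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}

STRUCTURAL_CATEGORIES = frozenset(
    {"active_site", "tunnel", "FAD_proximal", "NADPH_shell1", "NADPH_shell2", "other"}
)
LOCATIONS = frozenset({"surface", "core"})
DOMAINS = frozenset({"FAD_binding", "NADPH_binding", "insertion_80res"})


class AlignmentError(ValueError):
    pass


class TreeError(ValueError):
    pass


class Alignment:
    """A gapped protein alignment: ordered unique ids over a character matrix.

    The alphabet is the 20 amino acids plus the gap character '-'; 'X' is
    permitted and flagged as unknown.
    """

    def __init__(self, ids: list[str], sequences: list[str]):
        if len(ids) != len(sequences):
            raise AlignmentError("ids and sequences differ in length")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if not sequences:
            raise AlignmentError("empty alignment")
        n = len(sequences[0])
        for sid, seq in zip(ids, sequences):
            if len(seq) != n:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(seq)}, expected {n}"
                )
            for j, ch in enumerate(seq):
                if ch not in _ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {j + 1}"
                    )
        self.ids = list(ids)
        self.matrix = np.array([list(s) for s in sequences], dtype="<U1")
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        if (self.matrix == UNKNOWN).any():
            warnings.warn("alignment contains unknown residues 'X'", stacklevel=2)

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> str:
        try:
            i = self._index[seq_id]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from None
        return "".join(self.matrix[i])

    def column(self, col: int) -> str:
        """Alignment column (1-based) as a string over sequences in order."""
        if not 1 <= col <= self.n_sites:
            raise AlignmentError(f"column {col} outside 1..{self.n_sites}")
        return "".join(self.matrix[:, col - 1])

    def subset(self, ids: list[str]) -> "Alignment":
        return Alignment(list(ids), [self.row(i) for i in ids])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and bool((self.matrix == other.matrix).all())
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_seqs} sequences x {self.n_sites} sites)"


def read_fasta(path) -> Alignment:
    """Read a gapped protein FASTA file into an :class:`Alignment`.

    Lowercase is normalised to uppercase; '.' gaps are normalised to '-'.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper().replace(".", GAP))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids, seqs)


def write_fasta(alignment: Alignment, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(alignment.row(sid)), id=sid, description="")
        for sid in alignment.ids
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_phylip(alignment: Alignment, path) -> None:
    """Relaxed PHYLIP writer (name, two spaces, full sequence per line)."""
    with open(path, "w") as fh:
        fh.write(f" {alignment.n_seqs} {alignment.n_sites}\n")
        for sid in alignment.ids:
            fh.write(f"{sid}  {alignment.row(sid)}\n")


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    """One node of a rooted phylogeny."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode" | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        kind = "leaf" if self.is_leaf else "internal"
        return f"TreeNode({self.label!r}, {kind}, t={self.length})"


class PhyloTree:
    """Rooted tree with branch lengths in expected substitutions per site."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(f"missing branch length above {node.label!r}")
            if not np.isfinite(node.length) or node.length < 0:
                raise TreeError(
                    f"invalid branch length {node.length} above {node.label!r}"
                )

    def postorder(self):
        out = []

        def walk(n):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def preorder(self):
        out = []

        def walk(n):
            out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label: str) -> TreeNode:
        for n in self.postorder():
            if n.label == label:
                return n
        raise TreeError(f"no node labeled {label!r}")

    def copy(self) -> "PhyloTree":
        def clone(n):
            m = TreeNode(n.label, n.length)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return PhyloTree(clone(self.root))

    def to_newick(self) -> str:
        def fmt_label(label):
            if label is None:
                return ""
            if any(c in label for c in " ():;,'[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(n):
            if n.is_leaf:
                s = fmt_label(n.label)
            else:
                s = "(" + ",".join(walk(c) for c in n.children) + ")"
                s += fmt_label(n.label)
            if n.length is not None:
                s += f":{n.length:.10g}"
            return s

        return walk(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode):
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def read_newick(path) -> PhyloTree:
    """Read a single rooted Newick tree with branch lengths."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick file {path}: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"could not parse Newick string: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Coordinate bookkeeping


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional map between alignment columns and ungapped residue
    positions of one named sequence (both 1-based)."""

    seq_id: str
    col_to_res: dict[int, int]
    res_to_col: dict[int, int]

    def residue(self, col: int) -> int | None:
        """Residue position for an alignment column, or None on a gap column."""
        return self.col_to_res.get(col)

    def column(self, res: int) -> int:
        try:
            return self.res_to_col[res]
        except KeyError:
            raise KeyError(
                f"residue {res} outside 1..{len(self.res_to_col)} "
                f"for {self.seq_id!r}"
            ) from None


def build_coordinate_map(alignment: Alignment, seq_id: str) -> CoordinateMap:
    row = alignment.row(seq_id)
    col_to_res, res_to_col = {}, {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            res += 1
            col_to_res[col] = res
            res_to_col[res] = col
    return CoordinateMap(seq_id, col_to_res, res_to_col)


def coordinate_map_from_mask(seq_id: str, present: np.ndarray) -> CoordinateMap:
    """Coordinate map for a reconstructed ancestor given its presence mask."""
    col_to_res, res_to_col = {}, {}
    res = 0
    for col, p in enumerate(np.asarray(present, dtype=bool), start=1):
        if p:
            res += 1
            col_to_res[col] = res
            res_to_col[res] = col
    return CoordinateMap(seq_id, col_to_res, res_to_col)


# ---------------------------------------------------------------------------
# Structural annotations


@dataclass(frozen=True)
class ResidueAnnotation:
    position: int  # 1-based ungapped residue numbering of the ancestor
    category: str  # structural category, e.g. active_site / tunnel / other
    location: str  # surface or core
    domain: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"annotation position {self.position} < 1")
        if self.category not in STRUCTURAL_CATEGORIES:
            raise ValueError(f"unknown structural category {self.category!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.domain is not None and self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


def read_annotations(path) -> dict[int, ResidueAnnotation]:
    """Read a tab-delimited annotation table.

    Expected header: ``position<TAB>category<TAB>location<TAB>domain``
    (domain may be empty).
    """
    annotations: dict[int, ResidueAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["position", "category", "location"]:
            raise ValueError(
                f"unexpected annotation header {header!r}; expected "
                "position/category/location[/domain]"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            pos = int(parts[0])
            domain = parts[3] if len(parts) > 3 and parts[3] else None
            if pos in annotations:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos}")
            annotations[pos] = ResidueAnnotation(pos, parts[1], parts[2], domain)
    return annotations


def write_annotations(annotations: dict[int, ResidueAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcategory\tlocation\tdomain\n")
        for pos in sorted(annotations):
            a = annotations[pos]
            fh.write(f"{a.position}\t{a.category}\t{a.location}\t{a.domain or ''}\n")
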