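"""Readers, writers and validated in-memory containers for the formats the
pipeline touches: FASTA, Newick, the classic 12-column BLAST-tabular dialect,
and plain TSV presence/absence matrices.

Sequence parsing is delegated to Biopython and tree parsing to dendropy;
the thin wrappers here add the validation the downstream modules rely on
(unique tip labels, nonnegative branch lengths, strict column counts) and
normalise everything into the package's own containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import dendropy
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
NUCLEOTIDE_LETTERS = set("ACGTUNRYKMSWBDHV")


class FormatError(ValueError):
    """A malformed input file; the message names the offending record/line."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One FASTA record.

    ``alphabet_kind`` is ``"protein"`` or ``"nucleotide"``; ``aligned``
    permits the gap symbol ``-`` in ``residues``.
    """

    id: str
    residues: str
    description: str = ""
    alphabet_kind: str = "protein"
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def validate_alphabet(self) -> None:
        allowed = PROTEIN_LETTERS if self.alphabet_kind == "protein" else NUCLEOTIDE_LETTERS
        if self.aligned:
            allowed = allowed | {"-"}
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r} contains letters {sorted(bad)} outside the "
                f"{self.alphabet_kind} alphabet"
            )


def _as_text_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return io.StringIO(source)


def parse_fasta(source, alphabet_kind: str = "protein", aligned: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA stream (or string) into :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated; record order is preserved.
    A header with no sequence raises :class:`FormatError` naming the record.
    """
    records: list[SequenceRecord] = []
    for title, seq in SimpleFastaParser(_as_text_stream(source)):
        parts = title.split(None, 1)
        rec_id = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        if not seq:
            raise FormatError(f"record {rec_id!r} has an empty sequence")
        records.append(
            SequenceRecord(id=rec_id, residues=seq, description=desc,
                           alphabet_kind=alphabet_kind, aligned=aligned)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], handle: TextIO, width: int = 80) -> None:
    """Write records in FASTA, wrapping residues at ``width`` columns."""
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        handle.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            handle.write(rec.residues[i:i + width] + "\n")


def format_fasta(records: Iterable[SequenceRecord], width: int = 80) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree; ``length`` is the branch to the parent."""

    __slots__ = ("label", "length", "parent", "children", "age")

    def __init__(self, label: str = "", length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.age: float | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, {self.length})"


class AnnotatedTree:
    """Rooted tree with branch lengths and optional per-node ages.

    Internal nodes without labels receive deterministic preorder IDs
    ("n0", "n1", ...) at construction so per-branch reports are stable.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_internal_ids()
        labels = [t.label for t in self.tips()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise FormatError(f"duplicate tip labels: {sorted(dupes)}")

    def _assign_internal_ids(self) -> None:
        for i, node in enumerate(self.preorder()):
            if not node.is_tip and not node.label:
                node.label = f"n{i}"

    # traversals -----------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def node(self, label: str) -> TreeNode:
        for n in self.preorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def depth(self, node: TreeNode) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    def copy(self) -> "AnnotatedTree":
        def clone(n: TreeNode) -> TreeNode:
            c = TreeNode(n.label, n.length)
            c.age = n.age
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return AnnotatedTree(clone(self.root))

    # serialisation --------------------------------------------------------
    def to_newick(self, include_internal_labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.label if include_internal_labels else ""
                body = f"({inner}){label}"
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"


def parse_newick(source) -> AnnotatedTree:
    """Parse a single Newick tree with branch lengths.

    Raises :class:`FormatError` on unbalanced parentheses, duplicate tip
    labels, or negative branch lengths.
    """
    text = source.read() if hasattr(source, "read") else source
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = ""
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise FormatError(f"negative branch length {length} at node {label!r}")
        node = TreeNode(label, length if dnode.parent_node is not None else 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return AnnotatedTree(convert(dtree.seed_node))


def write_newick(tree: AnnotatedTree, handle: TextIO) -> None:
    handle.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# BLAST-tabular hits
# ---------------------------------------------------------------------------

#: the classic 12-column order
HIT_COLUMNS = (
    "query_id", "subject_id", "pident", "aln_length", "mismatches", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column BLAST-tabular file.

    Coordinates are carried as emitted by the aligner (1-based, inclusive)
    and never re-interpreted.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.pident <= 100.0:
            raise FormatError(f"pident {self.pident} outside [0, 100]")
        if self.aln_length <= 0:
            raise FormatError(f"aln_length {self.aln_length} must be positive")

    def to_line(self) -> str:
        return "\t".join([
            self.query_id, self.subject_id, f"{self.pident:.2f}",
            str(self.aln_length), str(self.mismatches), str(self.gapopen),
            str(self.qstart), str(self.qend), str(self.sstart), str(self.send),
            f"{self.evalue:.3g}", f"{self.bitscore:.1f}",
        ])


def parse_hits(source) -> list[AlignmentHit]:
    """Parse a 12-column BLAST-tabular stream.

    Lines beginning with ``#`` are skipped.  A line with the wrong column
    count, or a non-numeric numeric field, raises :class:`FormatError`
    citing the 1-based line number.  Extra columns are rejected rather than
    ignored so aligner-dialect misalignment fails loudly.
    """
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(_as_text_stream(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, found {len(fields)}"
            )
        try:
            hit = AlignmentHit(
                query_id=fields[0], subject_id=fields[1],
                pident=float(fields[2]), aln_length=int(fields[3]),
                mismatches=int(fields[4]), gapopen=int(fields[5]),
                qstart=int(fields[6]), qend=int(fields[7]),
                sstart=int(fields[8]), send=int(fields[9]),
                evalue=float(fields[10]), bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits(hits: Iterable[AlignmentHit], handle: TextIO) -> None:
    for hit in hits:
        handle.write(hit.to_line() + "\n")


# ---------------------------------------------------------------------------
# Binary presence/absence matrices
# ---------------------------------------------------------------------------

class BinaryContentMatrix:
    """Taxa x ortholog-group presence/absence matrix backed by a DataFrame.

    Rows are taxa, columns are OG identifiers, cells are 0/1.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise FormatError("taxon and OG identifiers must be unique")
        if frame.isna().any().any():
            raise FormatError("matrix has missing cells")
        values = frame.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise FormatError("matrix cells must be 0 or 1")
        self.frame = frame.astype("int8")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def og_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def to_tsv(self, handle: TextIO) -> None:
        self.frame.to_csv(handle, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, source) -> "BinaryContentMatrix":
        frame = pd.read_csv(_as_text_stream(source), sep="\t", index_col=0)
        return cls(frame)

    @classmethod
    def from_arrays(cls, taxon_ids, og_ids, cells) -> "BinaryContentMatrix":
        return cls(pd.DataFrame(cells, index=list(taxon_ids), columns=list(og_ids)))
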