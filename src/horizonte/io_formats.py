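"""Sequence and tree containers plus readers/writers for FASTA and Newick.

The two containers defined here — :class:`SequenceRecord` and
:class:`LabeledTree` — are the currency of every other module: TE copies and
consensus sequences travel as records, host trees / TE trees / area-bearing
trees travel as labeled rooted trees.  Parsing is delegated to Biopython
(FASTA) and DendroPy (Newick); the containers themselves stay deliberately
small so the parsimony dynamic programs can walk them directly.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, NewickError

# IUPAC nucleotide one-letter codes, the hard gap, and N.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV-")

PolytomyPolicy = Literal["reject", "resolve"]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, possibly gapped (alignment row).

    Residues are normalised to upper case; ``.`` is normalised to ``-``.
    Characters outside the IUPAC alphabet raise :class:`FormatError`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} is empty")
        norm = self.residues.upper().replace(".", "-")
        bad = set(norm) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal characters: "
                + ",".join(sorted(bad))
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        """Residues with gap characters removed."""
        return self.residues.replace("-", "")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of records, order preserved.

    Raises :class:`FormatError` on an empty file, duplicate ids or illegal
    residue characters, naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted tree.  ``name`` is mandatory for leaves."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class LabeledTree:
    """Rooted tree with uniquely named leaves and optional branch lengths.

    After construction the tree is validated: exactly one root, unique leaf
    names, branch lengths non-negative.  Binarity is required by the
    parsimony modules and can be checked with :meth:`is_binary` or enforced
    at parse time via the polytomy policy.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise NewickError("every leaf must carry a name")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NewickError(f"duplicate leaf names: {', '.join(dup)}")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise NewickError(
                    f"negative branch length at node {node.name!r}")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]  # type: ignore[misc]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def copy(self) -> "LabeledTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return LabeledTree(clone(self.root))


def _from_dendropy(node: dendropy.Node) -> TreeNode:
    name = None
    if node.taxon is not None:
        name = node.taxon.label
    elif node.label:
        name = node.label
    out = TreeNode(name=name, length=node.edge.length)
    for child in node.child_nodes():
        out.add_child(_from_dendropy(child))
    return out


def _resolve_polytomies(node: TreeNode) -> None:
    """Arbitrary left-ladder binarisation with zero-length edges, in place."""
    for child in node.children:
        _resolve_polytomies(child)
    while len(node.children) > 2:
        a = node.children.pop(0)
        b = node.children.pop(0)
        joint = TreeNode(name=None, length=0.0)
        joint.add_child(a)
        joint.add_child(b)
        joint.parent = node
        node.children.insert(0, joint)


def read_newick(text: str, polytomy: PolytomyPolicy = "reject") -> LabeledTree:
    """Parse a Newick string into a :class:`LabeledTree`.

    ``polytomy`` selects the policy for nodes with more than two children:
    ``"reject"`` (default) raises :class:`NewickError`, ``"resolve"``
    binarises them arbitrarily with zero-length internal edges.  Both
    parsimony dynamic programs in this package assume binary trees, hence
    the conservative default.
    """
    if not text.strip():
        raise NewickError("empty Newick string")
    if not text.rstrip().endswith(";"):
        raise NewickError("Newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick string: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    if polytomy == "reject":
        tmp = LabeledTree(root)
        for node in tmp.postorder():
            if len(node.children) > 2:
                raise NewickError(
                    f"polytomy with {len(node.children)} children at node "
                    f"{node.name or '<unnamed>'} (policy 'reject')")
        # A root with a single child (common artefact) is also rejected as
        # non-binary unless it is the trivial one-leaf tree.
        return tmp
    elif polytomy == "resolve":
        _resolve_polytomies(root)
        return LabeledTree(root)
    raise ValueError(f"unknown polytomy policy {polytomy!r}")


def read_newick_file(path: str | Path,
                     polytomy: PolytomyPolicy = "reject") -> LabeledTree:
    return read_newick(Path(path).read_text(), polytomy=polytomy)


def write_newick(tree: LabeledTree) -> str:
    """Serialise a tree as a Newick string (names and branch lengths)."""
    buf = _stdio.StringIO()

    def emit(node: TreeNode) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(child)
            buf.write(")")
        if node.name:
            buf.write(_quote_label(node.name))
        if node.length is not None:
            buf.write(f":{node.length:g}")

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
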