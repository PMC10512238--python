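"""Gene trees: Newick parsing, validation, and species annotation.

A *gene tree* is the phylogeny of one input protein's homolog family.  Leaves
are homolog identifiers whose species is recoverable from the label (by
default the token before the first ``"_"``, the usual proteome-header
convention).  Species annotation is a prerequisite for the species-overlap
duplication calls made downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Iterator

from skbio import TreeNode
from skbio.io import FormatIdentificationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTree",
    "ProteinSet",
    "NewickParseError",
    "SpeciesAnnotationError",
    "parse_newick",
    "annotate_species",
    "prefix_species_rule",
    "read_newick_file",
    "read_fasta",
]

#: Branch length substituted when the Newick string carries none.  Distances
#: computed in this package are purely topological, so the value only affects
#: plotting.
DEFAULT_BRANCH_LENGTH = 1.0

# Extended IUPAC amino-acid alphabet, X and stop allowed.
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJUOX*-")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


class SpeciesAnnotationError(ValueError):
    """Raised when leaf labels do not match the species-parsing rule."""


@dataclass
class GeneTree:
    """A rooted, species-annotatable phylogenetic tree for one gene.

    Parameters
    ----------
    gene_id : str
        Identifier of the seed protein the tree belongs to.
    tree : skbio.TreeNode
        Rooted topology; polytomies are preserved.
    species : dict or None
        Mapping leaf label -> species identifier, filled by
        :func:`annotate_species`.
    """

    gene_id: str
    tree: TreeNode
    species: dict[str, str] | None = field(default=None)

    def leaf_labels(self) -> list[str]:
        return [tip.name for tip in self.tree.tips()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def species_set(self) -> frozenset[str]:
        if self.species is None:
            raise SpeciesAnnotationError(
                f"gene tree {self.gene_id!r} is not species-annotated"
            )
        return frozenset(self.species.values())

    def copy(self) -> "GeneTree":
        return GeneTree(
            gene_id=self.gene_id,
            tree=self.tree.copy(),
            species=dict(self.species) if self.species is not None else None,
        )

    def to_newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class ProteinSet:
    """Ordered set of (protein_id, amino-acid sequence) records."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.records]
        if any(not pid for pid in ids):
            raise ValueError("protein ids must be non-empty")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        for pid, seq in self.records:
            bad = set(seq.upper()) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"protein {pid!r}: non-amino-acid characters {sorted(bad)}"
                )

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)


def parse_newick(text: str, gene_id: str = "gene") -> GeneTree:
    """Parse a single Newick statement into a :class:`GeneTree`.

    Topology and branch lengths are preserved exactly; polytomies are kept,
    never arbitrarily resolved.  Missing branch lengths are replaced by
    :data:`DEFAULT_BRANCH_LENGTH` with a warning.

    Raises
    ------
    NewickParseError
        On malformed input (unbalanced parentheses, empty leaf label,
        missing ";", negative branch length, duplicate leaf labels).
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must be terminated by ';'")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FormatIdentificationWarning)
            tree = TreeNode.read(
                StringIO(stripped), format="newick", convert_underscores=False
            )
    except Exception as exc:  # skbio NewickFormatError carries the position
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    labels = [tip.name for tip in tree.tips()]
    if any(label is None or label == "" for label in labels):
        raise NewickParseError("empty leaf label in Newick string")
    if len(labels) < 2:
        raise NewickParseError("a gene tree needs at least 2 leaves")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")

    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = DEFAULT_BRANCH_LENGTH
            defaulted += 1
        elif node.length < 0:
            raise NewickParseError(
                f"negative branch length {node.length} on {node.name!r}"
            )
    if defaulted:
        logger.warning(
            "%s: %d branch length(s) missing; defaulted to %.1f",
            gene_id, defaulted, DEFAULT_BRANCH_LENGTH,
        )
    return GeneTree(gene_id=gene_id, tree=tree)


def prefix_species_rule(delimiter: str = "_") -> Callable[[str], str]:
    """Species = leaf-label prefix up to the first *delimiter* (strict).

    The returned callable raises ``ValueError`` when the delimiter is absent
    or the prefix empty, so that unannotatable labels are surfaced rather
    than silently treated as their own species.
    """

    def rule(label: str) -> str:
        head, sep, _ = label.partition(delimiter)
        if not sep or not head:
            raise ValueError(label)
        return head

    return rule


def annotate_species(
    gene_tree: GeneTree,
    rule: Callable[[str], str] | None = None,
) -> GeneTree:
    """Return a copy of *gene_tree* with every leaf assigned a species.

    Parameters
    ----------
    rule : callable, optional
        Maps a leaf label to its species token.  Defaults to
        ``prefix_species_rule("_")``.

    Raises
    ------
    SpeciesAnnotationError
        Listing every leaf label the rule rejects.
    """
    if rule is None:
        rule = prefix_species_rule()
    mapping: dict[str, str] = {}
    offending: list[str] = []
    for label in gene_tree.leaf_labels():
        try:
            mapping[label] = rule(label)
        except ValueError:
            offending.append(label)
    if offending:
        raise SpeciesAnnotationError(
            f"leaf labels not matching the species rule: {offending}"
        )
    return GeneTree(gene_id=gene_tree.gene_id, tree=gene_tree.tree.copy(),
                    species=mapping)


def read_newick_file(path, gene_id: str | None = None) -> GeneTree:
    """Read one Newick tree from *path*; gene id defaults to the file stem."""
    from pathlib import Path

    p = Path(path)
    text = p.read_text().strip()
    return parse_newick(text, gene_id=gene_id or p.stem)


def read_fasta(path) -> ProteinSet:
    """Read a protein FASTA file into a :class:`ProteinSet`."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinSet(records)
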