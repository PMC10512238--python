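"""Pairwise gene-tree distances: strict (topological) and evolutionary.

Both distances compare two gene trees after decomposing each into
duplication-free subtrees:

1.  Every internal node is labelled a *duplication* when the species sets of
    its child clades overlap, and a *speciation* otherwise (species-overlap
    criterion).
2.  Each tree is recursively split at its duplication nodes into the forest
    of duplication-free resolutions (one paralog lineage kept per
    duplication, the speciation backbone kept intact), so no subtree carries
    a species more than once.
3.  Every subtree pair (one from each forest) sharing at least 4 species is
    restricted to the shared species and scored by the Robinson–Foulds (RF)
    distance of the unrooted restrictions, normalised by its maximum — the
    total number of non-trivial splits in the two restricted trees, which for
    two binary trees on n leaves equals 2*(n-3).

The *strict* distance is the mean normalised RF over evaluated pairs.  The
*evolutionary* (speciation) distance additionally penalises non-shared
species: each pair scores ``1 - (1 - RFnorm) * |shared| / max(|S_p|, |S_q|)``
where S_p, S_q are the species sets of the two subtrees.  If no subtree pair
is evaluable the distance is undefined and reported as NaN, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import GeneTree, SpeciesAnnotationError, annotate_species

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrixSet",
    "PrunedForest",
    "annotate_duplications",
    "prune_to_forest",
    "strict_distance",
    "evolutionary_distance",
    "pairwise_matrices",
]

#: Minimum number of shared species for a subtree pair to enter the mean.
MIN_SHARED_SPECIES = 4

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class PrunedForest:
    """Duplication-free decomposition of one gene tree.

    ``subtrees`` holds, per duplication-free piece, the frozen species set and
    the list of clades expressed as species sets (one leaf per species within
    a piece, so leaves and species are interchangeable).
    """

    source_gene_id: str
    subtrees: list["_Subtree"]


@dataclass
class _Subtree:
    species: frozenset[str]
    clades: list[frozenset[str]]  # species set of every node's clade


def annotate_duplications(gene_tree: GeneTree) -> GeneTree:
    """Label every internal node ``speciation`` or ``duplication``.

    A node is a duplication iff the species sets of (any two of) its child
    clades intersect.  The input must be species-annotated; the returned tree
    carries ``node.event`` on internal nodes and ``node.species_set`` on all
    nodes.
    """
    if gene_tree.species is None:
        raise SpeciesAnnotationError(
            f"gene tree {gene_tree.gene_id!r} must be species-annotated "
            "before duplication detection"
        )
    gt = gene_tree.copy()
    for node in gt.tree.postorder():
        if node.is_tip():
            node.species_set = frozenset({gt.species[node.name]})
        else:
            child_sets = [c.species_set for c in node.children]
            union: set[str] = set()
            dup = False
            for cs in child_sets:
                if union & cs:
                    dup = True
                union |= cs
            node.species_set = frozenset(union)
            node.event = DUPLICATION if dup else SPECIATION
    return gt


#: Safety cap on the number of duplication-free resolutions kept per tree
#: (2**n_duplications grows fast in heavily duplicated families).
MAX_RESOLUTIONS = 64


def prune_to_forest(gene_tree: GeneTree) -> PrunedForest:
    """Decompose a duplication-annotated tree into duplication-free subtrees.

    Splitting happens at every duplication node: each child clade of a
    duplication is one alternative paralog lineage, so the forest enumerates
    every resolution of the tree that keeps one lineage per duplication and
    the speciation backbone around it intact.  Each resulting subtree
    contains no duplication node and hence (species-overlap criterion) no
    species more than once; a single-copy tree comes back whole as a forest
    of one.  At most :data:`MAX_RESOLUTIONS` resolutions are kept, with a
    warning when the cap truncates.
    """
    root = gene_tree.tree
    if not hasattr(root, "species_set"):
        gene_tree = annotate_duplications(gene_tree)
        root = gene_tree.tree

    def resolve(node) -> list[tuple[frozenset, list[frozenset]]]:
        """All duplication-free (species set, clade list) resolutions."""
        if node.is_tip():
            sp = node.species_set
            return [(sp, [sp])]
        if node.event == DUPLICATION:
            # one paralog lineage survives per resolution
            out = []
            for child in node.children:
                out.extend(resolve(child))
            return out[:MAX_RESOLUTIONS]
        # speciation: children have pairwise disjoint species sets; take the
        # cartesian product of their resolutions
        combos = [(frozenset(), [])]
        for child in node.children:
            child_alts = resolve(child)
            combos = [
                (sp | c_sp, clades + c_clades)
                for sp, clades in combos
                for c_sp, c_clades in child_alts
            ][:MAX_RESOLUTIONS]
        return [(sp, clades + [sp]) for sp, clades in combos]

    alts = resolve(root)
    if len(alts) >= MAX_RESOLUTIONS:
        logger.warning(
            "%s: duplication-free resolutions capped at %d",
            gene_tree.gene_id, MAX_RESOLUTIONS,
        )
    subtrees = [_Subtree(species=sp, clades=clades) for sp, clades in alts]
    return PrunedForest(source_gene_id=gene_tree.gene_id, subtrees=subtrees)


def _splits_restricted(
    clades: list[frozenset[str]], shared: frozenset[str]
) -> set[frozenset[frozenset[str]]]:
    """Non-trivial unrooted bipartitions of a subtree restricted to *shared*.

    Restriction of a tree to a leaf subset induces, clade by clade, exactly
    the splits of the pruned tree; trivial (size < 2 on either side) and
    duplicate splits are dropped, which also absorbs the root edge.
    """
    n = len(shared)
    out: set[frozenset[frozenset[str]]] = set()
    for clade in clades:
        side = clade & shared
        if 2 <= len(side) <= n - 2:
            out.add(frozenset((side, shared - side)))
    return out


def _pair_rf_norm(p: _Subtree, q: _Subtree, shared: frozenset[str]) -> float:
    """Normalised RF of two duplication-free subtrees on their shared species."""
    sp = _splits_restricted(p.clades, shared)
    sq = _splits_restricted(q.clades, shared)
    denom = len(sp) + len(sq)
    if denom == 0:  # both restrictions are stars: identical topologies
        return 0.0
    return len(sp ^ sq) / denom


def _forest_pair_scores(a: PrunedForest, b: PrunedForest):
    """Yield (rf_norm, shared, p, q) over evaluable subtree pairs."""
    for p in a.subtrees:
        for q in b.subtrees:
            shared = p.species & q.species
            if len(shared) < MIN_SHARED_SPECIES:
                continue
            yield _pair_rf_norm(p, q, shared), shared, p, q


def _ensure_forest(t: GeneTree | PrunedForest) -> PrunedForest:
    if isinstance(t, PrunedForest):
        return t
    return prune_to_forest(annotate_duplications(t))


def strict_distance(a: GeneTree | PrunedForest, b: GeneTree | PrunedForest) -> float:
    """Mean normalised RF over duplication-free subtree pairs; NaN if none.

    Symmetric, in [0, 1]; 0 for identical single-copy trees and NaN (never a
    silent 0) when the trees share fewer than 4 species in every subtree pair.
    """
    fa, fb = _ensure_forest(a), _ensure_forest(b)
    scores = [s for s, *_ in _forest_pair_scores(fa, fb)]
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def evolutionary_distance(
    a: GeneTree | PrunedForest, b: GeneTree | PrunedForest
) -> float:
    """Speciation-history-aware distance; NaN when no subtree pair qualifies.

    Per subtree pair the topological agreement ``1 - RFnorm`` is discounted
    by the species-overlap fraction, so missing species push the score toward
    1 even when the shared part agrees perfectly.
    """
    fa, fb = _ensure_forest(a), _ensure_forest(b)
    scores = []
    for rf_norm, shared, p, q in _forest_pair_scores(fa, fb):
        overlap = len(shared) / max(len(p.species), len(q.species))
        scores.append(1.0 - (1.0 - rf_norm) * overlap)
    if not scores:
        return float("nan")
    return float(np.mean(scores))


@dataclass
class DistanceMatrixSet:
    """Strict, evolutionary, and (derived) combined gene–gene distances.

    All matrices are symmetric with a zero diagonal; undefined entries are
    NaN (serialized as "NA").  ``combined`` is None until filled by
    :func:`coevoclust.coevo.combine_matrices`.
    """

    gene_ids: list[str]
    strict: np.ndarray
    evolutionary: np.ndarray
    combined: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = len(self.gene_ids)
        for name in ("strict", "evolutionary", "combined"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            setattr(self, name, m)
            if m.shape != (d, d):
                raise ValueError(f"{name} matrix shape {m.shape} != ({d},{d})")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self, which: str) -> pd.DataFrame:
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"{which} matrix not computed")
        return pd.DataFrame(m, index=self.gene_ids, columns=self.gene_ids)

    def write_tsv(self, which: str, path) -> None:
        self.to_frame(which).to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def matrix_from_tsv(cls, path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def pairwise_matrices(trees: list[GeneTree]) -> DistanceMatrixSet:
    """All-vs-all strict and evolutionary distances for >= 2 gene trees.

    Trees lacking species annotation are annotated with the default
    prefix rule.  Row/column order follows the input order.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 gene trees")
    ids = [t.gene_id for t in trees]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be unique")

    forests = []
    for t in trees:
        if t.species is None:
            t = annotate_species(t)
        forests.append(prune_to_forest(annotate_duplications(t)))

    d = len(trees)
    strict = np.zeros((d, d))
    evo = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            s = strict_distance(forests[i], forests[j])
            e = evolutionary_distance(forests[i], forests[j])
            strict[i, j] = strict[j, i] = s
            evo[i, j] = evo[j, i] = e
            if np.isnan(s):
                logger.warning(
                    "no evaluable subtree pair for (%s, %s); distance is NA",
                    ids[i], ids[j],
                )
    return DistanceMatrixSet(gene_ids=ids, strict=strict, evolutionary=evo)
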