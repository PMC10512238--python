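"""Synthetic gene-tree families with controlled coevolution structure.

These generators stand in for the control sets used to calibrate the
method on real data: a *co-evolved* family shares one species-tree
topology up to a few nearest-neighbour-interchange (NNI) moves and optional
gene duplications, emulating enzymes of a conserved pathway; *independent*
genes get unrelated uniform-random topologies, emulating randomly assembled
gene sets.  :func:`make_benchmark_gc` combines both into an annotated
benchmark cluster so the full pipeline — distances, clustering, detection,
confusion counts — can be exercised end to end without any database.

Everything is deterministic per seed, and every emitted tree round-trips
through the Newick layer of :mod:`coevoclust.trees`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .evaluation import GeneAnnotation
from .trees import GeneTree

__all__ = [
    "SyntheticFamilyConfig",
    "simulate_species_tree",
    "simulate_coevolved_family",
    "simulate_independent_genes",
    "make_benchmark_gc",
]


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Study conditions of the synthetic benchmark cluster.

    Defaults describe a strong-signal regime: 16 species, 6 co-evolved
    genes one NNI move away from a shared topology, 3 independent genes,
    a 10% per-node duplication rate, and mild log-normal branch jitter.
    """

    n_species: int = 16
    n_coevolved: int = 6
    n_independent: int = 3
    nni_moves: int = 1
    duplication_rate: float = 0.1
    branch_jitter: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 8:
            raise ValueError("n_species must be >= 8")
        if self.n_coevolved + self.n_independent < 4:
            raise ValueError("need at least 4 genes in total")
        if self.nni_moves < 0:
            raise ValueError("nni_moves must be >= 0")
        if not (0.0 <= self.duplication_rate < 1.0):
            raise ValueError("duplication_rate must be in [0, 1)")


def _new_tip(name: str, rng) -> TreeNode:
    return TreeNode(name=name, length=float(rng.exponential(1.0)))


def _species_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def simulate_species_tree(n_species: int, seed: int) -> TreeNode:
    """Yule (pure-birth) species tree: rooted binary, exponential lengths.

    Starting from a two-species cherry, a uniformly chosen extant tip
    speciates until ``n_species`` tips exist — the standard equal-rates
    construction of a Yule topology.  Deterministic per seed.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    tips = []
    for _ in range(2):
        t = _new_tip("", rng)
        root.append(t)
        tips.append(t)
    while len(tips) < n_species:
        parent = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            t = _new_tip("", rng)
            parent.append(t)
            tips.append(t)
        parent.name = None
    for name, tip in zip(_species_names(n_species), root.tips()):
        tip.name = name
    return root


def _binary_internal_nodes(tree: TreeNode) -> list[TreeNode]:
    return [
        n for n in tree.traverse(include_self=False)
        if not n.is_tip() and len(n.children) == 2
    ]


def _nni(tree: TreeNode, rng) -> None:
    """One random NNI move in place: swap a child of an internal node with
    its sibling."""
    candidates = _binary_internal_nodes(tree)
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    c = v.children[int(rng.integers(len(v.children)))]
    u.remove(s)
    v.remove(c)
    u.append(c)
    v.append(s)


def _jitter_lengths(tree: TreeNode, sigma: float, rng) -> None:
    if sigma <= 0:
        return
    for node in tree.traverse(include_self=False):
        base = node.length if node.length is not None else 1.0
        node.length = float(base * rng.lognormal(mean=0.0, sigma=sigma))


def _insert_duplications(tree: TreeNode, rate: float, rng, tag: str) -> None:
    """Graft a copy of a subtree as its own sibling at ``rate`` per
    internal node; copied leaves get a uniquifying suffix."""
    if rate <= 0:
        return
    targets = [
        n for n in list(tree.traverse(include_self=False))
        if not n.is_tip() and rng.random() < rate
    ]
    for i, node in enumerate(targets):
        parent = node.parent
        dup = node.copy()
        for tip in dup.tips():
            tip.name = f"{tip.name}{tag}{i + 1}"
        joint = TreeNode(name=None, length=node.length)
        parent.remove(node)
        node.length = 0.1
        dup.length = 0.1
        joint.append(node)
        joint.append(dup)
        parent.append(joint)


def simulate_coevolved_family(
    base: TreeNode,
    n_genes: int,
    cfg: SyntheticFamilyConfig,
    rng=None,
    gene_prefix: str = "g",
    start_index: int = 1,
) -> list[GeneTree]:
    """Gene trees sharing the *base* topology up to noise.

    Each tree is a copy of the species tree perturbed by exactly
    ``cfg.nni_moves`` random NNI moves, log-normal branch jitter, and
    duplications inserted at ``cfg.duplication_rate`` per internal node
    (the duplicated subtree is grafted as its own sibling).  Leaves are
    labelled ``species_geneID`` so the default species rule applies.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    for i in range(n_genes):
        gid = f"{gene_prefix}{start_index + i}"
        t = base.copy()
        for _ in range(cfg.nni_moves):
            _nni(t, rng)
        _jitter_lengths(t, cfg.branch_jitter, rng)
        # tag duplicated copies before relabelling so suffixes stay unique
        for tip in t.tips():
            tip.name = f"{tip.name}_{gid}"
        _insert_duplications(t, cfg.duplication_rate, rng, tag="c")
        species = {tip.name: tip.name.partition("_")[0] for tip in t.tips()}
        out.append(GeneTree(gene_id=gid, tree=t, species=species))
    return out


def _uniform_rooted_topology(leaf_names: list[str], rng) -> TreeNode:
    """Uniform random rooted binary labelled topology by stepwise insertion.

    Each new leaf is attached to a uniformly chosen edge (including the
    root edge), which makes every rooted binary labelled shape equally
    likely.
    """
    names = list(leaf_names)
    root = TreeNode(name=None)
    a = TreeNode(name=names[0], length=float(rng.exponential(1.0)))
    b = TreeNode(name=names[1], length=float(rng.exponential(1.0)))
    root.append(a)
    root.append(b)
    for name in names[2:]:
        edges = list(root.traverse(include_self=False))
        choice = int(rng.integers(len(edges) + 1))  # +1: above the root
        leaf = TreeNode(name=name, length=float(rng.exponential(1.0)))
        if choice == len(edges):
            new_root = TreeNode(name=None)
            root.length = float(rng.exponential(1.0))
            new_root.append(root)
            new_root.append(leaf)
            root = new_root
        else:
            node = edges[choice]
            parent = node.parent
            joint = TreeNode(name=None, length=float(rng.exponential(1.0)))
            parent.remove(node)
            joint.append(node)
            joint.append(leaf)
            parent.append(joint)
    return root


def simulate_independent_genes(
    n_genes: int,
    n_species: int,
    seed: int,
    gene_prefix: str = "g",
    start_index: int = 1,
) -> list[GeneTree]:
    """Gene trees with mutually independent uniform-random topologies."""
    if n_species < 4:
        raise ValueError("n_species must be >= 4")
    rng = np.random.default_rng(seed)
    species = _species_names(n_species)
    out = []
    for i in range(n_genes):
        gid = f"{gene_prefix}{start_index + i}"
        topo = _uniform_rooted_topology(species, rng)
        for tip in topo.tips():
            tip.name = f"{tip.name}_{gid}"
        sp_map = {tip.name: tip.name.partition("_")[0] for tip in topo.tips()}
        out.append(GeneTree(gene_id=gid, tree=topo, species=sp_map))
    return out


def make_benchmark_gc(
    cfg: SyntheticFamilyConfig | None = None,
) -> tuple[list[GeneTree], list[GeneAnnotation]]:
    """An annotated synthetic benchmark cluster.

    Co-evolved genes come first: the first is the ``core`` anchor, the rest
    alternate ``biosynthetic`` / ``further_essential``.  Independent genes
    alternate ``gap`` / ``extra``.  The returned truth table feeds the
    evaluation module directly.
    """
    cfg = cfg or SyntheticFamilyConfig()
    rng = np.random.default_rng(cfg.seed)
    base = simulate_species_tree(cfg.n_species, seed=int(rng.integers(2**31)))
    coevolved = simulate_coevolved_family(
        base, cfg.n_coevolved, cfg, rng=rng, start_index=1
    )
    independent = simulate_independent_genes(
        cfg.n_independent,
        cfg.n_species,
        seed=int(rng.integers(2**31)),
        start_index=cfg.n_coevolved + 1,
    )
    trees = coevolved + independent

    annotations = []
    for i, gt in enumerate(coevolved):
        if i == 0:
            role = "core"
        else:
            role = "biosynthetic" if i % 2 == 1 else "further_essential"
        annotations.append(GeneAnnotation(gt.gene_id, role))
    for i, gt in enumerate(independent):
        annotations.append(GeneAnnotation(gt.gene_id, "gap" if i % 2 == 0 else "extra"))
    return trees, annotations
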