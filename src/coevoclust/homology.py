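"""Optional upstream stage: homolog search, alignment, and tree inference.

This module turns a protein FASTA into per-gene phylogenetic trees by
driving external tools — a similarity search engine (DIAMOND or BLAST), a
multiple aligner, and a tree builder — through small pluggable adapters.
Only the orchestration, hit parsing, and truncation logic live here; the
engines themselves are external binaries.  The whole stage is optional:
precomputed Newick trees bypass it entirely, and that is the mode the test
suite exercises (engine outputs are mocked as fixture tables).

Database guidance encoded in :func:`validate_database`: at least 25
distinct proteomes are required, because each gene tree is built from at
most the top 20 homologs and a smaller database would make trees
degenerate; the proteome sample should also be taxonomically
representative, which is surfaced as warnings, not errors.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .trees import GeneTree, ProteinSet, annotate_species, parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "DatabaseManifest",
    "HomologSet",
    "EngineError",
    "validate_database",
    "parse_tabular_hits",
    "search_homologs",
    "build_gene_trees",
    "MafftAligner",
    "FastTreeBuilder",
]

#: Homologs retained per seed protein.
TOP_HITS = 20
#: Minimum number of distinct proteomes in a searchable database.
MIN_PROTEOMES = 25

ENGINES = ("diamond", "blast")


class EngineError(RuntimeError):
    """An external tool is missing or failed."""


@dataclass
class DatabaseManifest:
    """Declared content of a proteome database.

    ``proteomes`` maps a proteome identifier (file or accession) to its
    species; ``clade_of`` optionally maps species to a higher taxonomic
    group, and ``expected_clades`` lists groups the database is supposed to
    represent.
    """

    proteomes: dict[str, str]
    clade_of: dict[str, str] = field(default_factory=dict)
    expected_clades: tuple[str, ...] = ()


def validate_database(manifest: DatabaseManifest,
                      min_proteomes: int = MIN_PROTEOMES) -> list[str]:
    """Hard-check proteome count, soft-check taxonomic representativeness.

    Returns the list of warnings; raises ``ValueError`` when fewer than
    ``min_proteomes`` proteomes are declared.
    """
    n = len(manifest.proteomes)
    if n < min_proteomes:
        raise ValueError(
            f"database lists {n} proteomes; at least {min_proteomes} are "
            f"required because trees use at most {TOP_HITS} homologs"
        )
    warnings: list[str] = []
    if manifest.clade_of:
        counts = Counter(
            manifest.clade_of.get(sp, "unassigned")
            for sp in manifest.proteomes.values()
        )
        for clade in manifest.expected_clades:
            if counts.get(clade, 0) == 0:
                warnings.append(f"expected clade {clade!r} has no proteome")
        top_share = max(counts.values()) / n
        if top_share > 0.5:
            dominant = max(counts, key=counts.get)
            warnings.append(
                f"clade {dominant!r} contributes {top_share:.0%} of proteomes; "
                "the sample may not be representative"
            )
    for w in warnings:
        logger.warning("database manifest: %s", w)
    return warnings


@dataclass
class HomologSet:
    """Top homologs of one seed protein, sorted by search score."""

    seed_protein_id: str
    hits: list[tuple[str, str, str]]  # (subject_id, species, sequence)

    def __post_init__(self) -> None:
        if len(self.hits) > TOP_HITS:
            raise ValueError(f"more than {TOP_HITS} hits retained")


def parse_tabular_hits(text: str) -> dict[str, list[tuple[str, float]]]:
    """Parse 12-column tabular search output (outfmt-6 style).

    Returns, per query id, the subject ids sorted by bitscore descending
    and truncated to the top 20.
    """
    raw: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        bitscore = float(fields[11])
        raw.setdefault(query, []).append((subject, bitscore))
    out = {}
    for query, hits in raw.items():
        hits.sort(key=lambda sb: -sb[1])
        out[query] = hits[:TOP_HITS]
    return out


def _engine_command(engine: str, query: Path, db: str, out: Path,
                    threads: int = 1) -> list[str]:
    if engine == "diamond":
        return [
            "diamond", "blastp", "--query", str(query), "--db", db,
            "--out", str(out), "--outfmt", "6", "--threads", str(threads),
        ]
    if engine == "blast":
        return [
            "blastp", "-query", str(query), "-db", db,
            "-out", str(out), "-outfmt", "6", "-num_threads", str(threads),
        ]
    raise ValueError(f"unknown search engine {engine!r}; choose from {ENGINES}")


def _default_runner(cmd: list[str]) -> None:
    binary = cmd[0]
    if shutil.which(binary) is None:
        raise EngineError(
            f"required binary {binary!r} not found on PATH; install it or "
            "switch to precomputed-trees mode"
        )
    res = subprocess.run(cmd, capture_output=True, text=True)
    if res.returncode != 0:
        raise EngineError(f"{binary} failed: {res.stderr.strip()[:500]}")


def search_homologs(
    proteins: ProteinSet,
    db: str,
    engine: str = "diamond",
    workdir: Path | str = ".",
    sequence_of: dict[str, tuple[str, str]] | None = None,
    threads: int = 1,
    runner=None,
) -> dict[str, HomologSet]:
    """Search every seed protein against the database; keep the top 20 hits.

    ``sequence_of`` maps subject id -> (species, sequence); in a real run it
    is backed by the database extraction step, in tests by a fixture dict.
    ``runner`` executes the engine command (injectable so parsing and
    truncation are testable without binaries).  Proteins with zero hits are
    flagged and excluded downstream with a warning.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown search engine {engine!r}; choose from {ENGINES}")
    runner = runner or _default_runner
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    query = workdir / "query.fasta"
    with open(query, "w") as fh:
        for pid, seq in proteins:
            fh.write(f">{pid}\n{seq}\n")
    out = workdir / f"{engine}_hits.tsv"
    runner(_engine_command(engine, query, db, out, threads))
    hits_by_query = parse_tabular_hits(out.read_text())

    results: dict[str, HomologSet] = {}
    for pid, _ in proteins:
        hits = hits_by_query.get(pid, [])
        if not hits:
            logger.warning("protein %s: zero database hits; excluded", pid)
            continue
        if len(hits) < 4:
            logger.warning(
                "protein %s: only %d hits; its tree will be small", pid, len(hits)
            )
        resolved = []
        for subject, _score in hits:
            if sequence_of is None or subject not in sequence_of:
                raise EngineError(
                    f"subject {subject!r} not extractable from the database"
                )
            species, seq = sequence_of[subject]
            resolved.append((subject, species, seq))
        results[pid] = HomologSet(seed_protein_id=pid, hits=resolved)
    return results


class MafftAligner:
    """Adapter running MAFFT on a FASTA file (default aligner)."""

    def __init__(self, runner=None):
        self.runner = runner

    def __call__(self, fasta: Path, out: Path) -> None:
        if self.runner is not None:
            self.runner(fasta, out)
            return
        if shutil.which("mafft") is None:
            raise EngineError("required binary 'mafft' not found on PATH")
        with open(out, "w") as fh:
            res = subprocess.run(
                ["mafft", "--auto", str(fasta)], stdout=fh,
                stderr=subprocess.PIPE, text=True,
            )
        if res.returncode != 0:
            raise EngineError(f"mafft failed: {res.stderr.strip()[:500]}")


class FastTreeBuilder:
    """Adapter running FastTree on an alignment (default tree builder)."""

    def __init__(self, runner=None):
        self.runner = runner

    def __call__(self, alignment: Path) -> str:
        if self.runner is not None:
            return self.runner(alignment)
        binary = shutil.which("fasttree") or shutil.which("FastTree")
        if binary is None:
            raise EngineError("required binary 'fasttree' not found on PATH")
        res = subprocess.run(
            [binary, str(alignment)], capture_output=True, text=True
        )
        if res.returncode != 0:
            raise EngineError(f"fasttree failed: {res.stderr.strip()[:500]}")
        return res.stdout.strip()


def build_gene_trees(
    homolog_sets: dict[str, HomologSet],
    proteins: ProteinSet,
    workdir: Path | str,
    aligner=None,
    tree_builder=None,
    species_delimiter: str = "_",
) -> list[GeneTree]:
    """One aligned, inferred, species-annotated tree per seed protein.

    Homolog leaves are written as ``species_subjectid`` so the default
    species rule applies.  A protein whose alignment or tree inference
    fails is excluded with a log record and the run continues; every tree
    is persisted as Newick next to its alignment.
    """
    aligner = aligner or MafftAligner()
    tree_builder = tree_builder or FastTreeBuilder()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seq_of_seed = dict(proteins.records)

    trees: list[GeneTree] = []
    for pid, hs in homolog_sets.items():
        try:
            fasta = workdir / f"{pid}.fasta"
            with open(fasta, "w") as fh:
                fh.write(f">seed{species_delimiter}{pid}\n{seq_of_seed[pid]}\n")
                for subject, species, seq in hs.hits:
                    clean = subject.replace(species_delimiter, "-")
                    fh.write(f">{species}{species_delimiter}{clean}\n{seq}\n")
            aln = workdir / f"{pid}.aln.fasta"
            aligner(fasta, aln)
            newick = tree_builder(aln)
            (workdir / f"{pid}.nwk").write_text(newick + "\n")
            gt = annotate_species(parse_newick(newick, gene_id=pid))
            trees.append(gt)
        except Exception as exc:
            logger.error("protein %s excluded: %s", pid, exc)
    return trees
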