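"""GWAS disease-gene network construction.

Trait-gene associations from an NHGRI-EBI GWAS-catalog-dialect table are
grouped into diseases by Medical Subject Headings (MeSH): a trait contributes
its mapped genes to every level-3 ancestor of its MeSH tree numbers inside the
Disease [C] category (a level-3 term is the first three dot-separated
components, e.g. C04.588.180). Each disease gene set can then be expanded with
at most `max_added` one-hop neighbors through high-confidence (combined score
strictly > 0.9) protein-protein interaction edges in the STRING links dialect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from ._util import mean_per_entity, normalize_symbol

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.9
DEFAULT_MAX_ADDED = 100

#: provenance tags
CATALOG = "catalog"
PPI_EXPANSION = "ppi_expansion"

_TREE_RE = re.compile(r"^[A-Z]\d{2}(\.\d{3})*$")
_LEVEL3_RE = re.compile(r"^C\d{2}(\.\d{3}){2}$")
# catalog multi-gene cells separate symbols with "," or " - " (intergenic pairs)
_GENE_SPLIT_RE = re.compile(r",|\s-\s")
_GENE_DROP = {"", "INTERGENIC", "NR", "NA"}


@dataclass(frozen=True)
class AssociationRecord:
    """One GWAS catalog row: a trait, its mapped gene symbols, and the study id."""

    trait: str
    genes: tuple[str, ...]
    study: str = ""


@dataclass(frozen=True)
class PPIEdge:
    """Undirected scored protein-protein interaction; score normalized to [0,1]."""

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


class NetworkSummary(NamedTuple):
    n_diseases: int
    n_genes: int
    n_interactions: int
    mean_genes_per_disease: int


@dataclass
class DiseaseGeneNetwork:
    """Bipartite disease-gene network keyed by level-3 MeSH Disease [C] terms."""

    diseases: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for disease_id in self.diseases:
            if not _LEVEL3_RE.match(disease_id):
                raise ValueError(f"disease id {disease_id!r} is not a level-3 C term")
            self.labels.setdefault(disease_id, disease_id)
            prov = self.provenance.setdefault(disease_id, {})
            for gene in self.diseases[disease_id]:
                prov.setdefault(gene, CATALOG)

    @property
    def disease_ids(self) -> list[str]:
        return sorted(self.diseases)

    def catalog_genes(self, disease_id: str) -> set[str]:
        prov = self.provenance[disease_id]
        return {g for g in self.diseases[disease_id] if prov.get(g, CATALOG) == CATALOG}

    def summary(self) -> NetworkSummary:
        """(diseases, distinct genes, interactions, mean genes/disease rounded)."""
        distinct: set[str] = set()
        interactions = 0
        for genes in self.diseases.values():
            distinct |= genes
            interactions += len(genes)
        n = len(self.diseases)
        return NetworkSummary(
            n, len(distinct), interactions, mean_per_entity(interactions, n) if n else 0
        )

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("disease_id\tdisease_label\tgene\tprovenance\n")
            for did in self.disease_ids:
                prov = self.provenance[did]
                for gene in sorted(self.diseases[did]):
                    fh.write(f"{did}\t{self.labels[did]}\t{gene}\t{prov.get(gene, CATALOG)}\n")

    def to_sif(self, path, relation: str = "interacts") -> None:
        """Simple interaction format for Cytoscape import."""
        with open(path, "w") as fh:
            for did in self.disease_ids:
                for gene in sorted(self.diseases[did]):
                    fh.write(f"{did}\t{relation}\t{gene}\n")


def read_disease_edges(path) -> DiseaseGeneNetwork:
    """Read a network back from the edge TSV written by :meth:`to_edge_tsv`."""
    edges = pd.read_csv(path, sep="\t", dtype=str)
    diseases: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    provenance: dict[str, dict[str, str]] = {}
    for row in edges.itertuples(index=False):
        diseases.setdefault(row.disease_id, set()).add(row.gene)
        labels[row.disease_id] = row.disease_label
        provenance.setdefault(row.disease_id, {})[row.gene] = row.provenance
    return DiseaseGeneNetwork(diseases, labels, provenance)


# ---------------------------------------------------------------------------
# parsing


def _split_genes(cell: str) -> tuple[str, ...]:
    genes = []
    for token in _GENE_SPLIT_RE.split(cell):
        symbol = normalize_symbol(token)
        if symbol not in _GENE_DROP:
            genes.append(symbol)
    return tuple(dict.fromkeys(genes))  # dedupe, keep order


def parse_gwas_catalog(
    source, include_reported: bool = False
) -> list[AssociationRecord]:
    """Parse a GWAS-catalog-dialect TSV into association records.

    `MAPPED_GENE` is the primary gene column; with ``include_reported`` the
    curated `REPORTED GENE(S)` column is unioned in. Multi-gene cells are split
    on the catalog separators ("," and " - "); empty and ``intergenic`` entries
    are dropped and symbols are uppercased.
    """
    table = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    for col in ("DISEASE/TRAIT", "MAPPED_GENE"):
        if col not in table.columns:
            raise ValueError(f"GWAS catalog is missing required column {col!r}")
    if include_reported and "REPORTED GENE(S)" not in table.columns:
        raise ValueError("GWAS catalog is missing required column 'REPORTED GENE(S)'")

    trait_col = table["DISEASE/TRAIT"]
    mapped_col = table["MAPPED_GENE"]
    reported_col = table["REPORTED GENE(S)"] if include_reported else None
    study_col = table["PUBMEDID"] if "PUBMEDID" in table.columns else None
    records = []
    for i in range(len(table)):
        trait = trait_col.iat[i].strip()
        if not trait:
            continue
        genes = list(_split_genes(mapped_col.iat[i]))
        if reported_col is not None:
            genes.extend(g for g in _split_genes(reported_col.iat[i]) if g not in genes)
        study = study_col.iat[i] if study_col is not None else ""
        records.append(AssociationRecord(trait, tuple(genes), study))
    return records


def mesh_level3(tree_number: str) -> str | None:
    """Truncate a MeSH tree number to its level-3 Disease [C] term.

    Returns None for non-C categories or depth < 3; raises on malformed input.
    """
    tree_number = tree_number.strip()
    if not _TREE_RE.match(tree_number):
        raise ValueError(f"malformed MeSH tree number {tree_number!r}")
    if not tree_number.startswith("C"):
        return None
    parts = tree_number.split(".")
    if len(parts) < 3:
        return None
    return ".".join(parts[:3])


def read_mesh_mapping(path) -> dict[str, tuple[str, list[str]]]:
    """Read a trait -> (MeSH unique id, tree numbers) TSV (trees ';'-separated)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("trait", "mesh_id", "tree_numbers"):
        if col not in table.columns:
            raise ValueError(f"MeSH mapping is missing required column {col!r}")
    mapping: dict[str, tuple[str, list[str]]] = {}
    for row in table.itertuples(index=False):
        trees = [t.strip() for t in row.tree_numbers.split(";") if t.strip()]
        mapping[row.trait.strip()] = (row.mesh_id.strip(), trees)
    return mapping


def aggregate_disease_genes(
    records: Iterable[AssociationRecord],
    mapping: Mapping[str, tuple[str, list[str]]],
) -> DiseaseGeneNetwork:
    """Group trait genes under every level-3 Disease [C] ancestor of their terms.

    Traits without a mapping, or whose tree numbers have no C-category level-3
    ancestor, are dropped (logged, not fatal). Gene sets are unions over all
    contributing traits, deduplicated.
    """
    diseases: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for record in records:
        entry = mapping.get(record.trait)
        if entry is None:
            unmapped.add(record.trait)
            continue
        _mesh_id, trees = entry
        ancestors = {a for a in (mesh_level3(t) for t in trees) if a is not None}
        if not ancestors:
            unmapped.add(record.trait)
            continue
        for ancestor in ancestors:
            diseases.setdefault(ancestor, set()).update(record.genes)
    if unmapped:
        logger.info(
            "%d traits dropped (no MeSH mapping or no Disease [C] level-3 ancestor)",
            len(unmapped),
        )
    return DiseaseGeneNetwork(diseases)


# ---------------------------------------------------------------------------
# PPI expansion


def read_string_links(path) -> list[PPIEdge]:
    """Read a STRING-links-dialect edge file (protein1 protein2 combined_score).

    Scores are integers 0-1000 in the file and are normalized to [0, 1].
    Self-loops are dropped with a log message.
    """
    table = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in ("protein1", "protein2", "combined_score"):
        if col not in table.columns:
            raise ValueError(f"STRING links file is missing required column {col!r}")
    edges = []
    n_loops = 0
    for row in table.itertuples(index=False):
        a = normalize_symbol(row.protein1)
        b = normalize_symbol(row.protein2)
        if a == b:
            n_loops += 1
            continue
        edges.append(PPIEdge(a, b, int(row.combined_score) / 1000.0))
    if n_loops:
        logger.info("dropped %d self-loop PPI edges", n_loops)
    return edges


def expand_with_ppi(
    network: DiseaseGeneNetwork,
    edges: Iterable[PPIEdge],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_added: int = DEFAULT_MAX_ADDED,
) -> DiseaseGeneNetwork:
    """Append up to `max_added` high-confidence one-hop PPI neighbors per disease.

    Candidates are neighbors of the catalog (seed) genes through edges with
    score strictly > `score_threshold`; they are ranked by the maximum edge
    score to the seed set (descending), ties broken by gene symbol, so the cap
    is deterministic. Seed genes are never duplicated and existing genes keep
    their provenance.
    """
    if not 0 < score_threshold <= 1:
        raise ValueError("score_threshold must be in (0, 1]")
    if max_added < 0:
        raise ValueError("max_added must be >= 0")

    adjacency: dict[str, list[tuple[str, float]]] = {}
    for edge in edges:
        if edge.score > score_threshold:
            adjacency.setdefault(edge.gene_a, []).append((edge.gene_b, edge.score))
            adjacency.setdefault(edge.gene_b, []).append((edge.gene_a, edge.score))

    diseases: dict[str, set[str]] = {}
    provenance: dict[str, dict[str, str]] = {}
    for did in network.disease_ids:
        seeds = network.catalog_genes(did)
        current = set(network.diseases[did])
        best: dict[str, float] = {}
        for seed in seeds:
            for neighbor, score in adjacency.get(seed, ()):
                if neighbor in current:
                    continue
                if score > best.get(neighbor, -1.0):
                    best[neighbor] = score
        # budget counts genes already added by a previous expansion, so the
        # total non-catalog complement never exceeds max_added
        budget = max(0, max_added - (len(current) - len(seeds)))
        ranked = sorted(best, key=lambda g: (-best[g], g))[:budget]
        diseases[did] = current | set(ranked)
        prov = dict(network.provenance[did])
        for gene in ranked:
            prov[gene] = PPI_EXPANSION
        provenance[did] = prov
    return DiseaseGeneNetwork(diseases, dict(network.labels), provenance)


def network_summary(network: DiseaseGeneNetwork) -> NetworkSummary:
    """Functional alias for :meth:`DiseaseGeneNetwork.summary`."""
    return network.summary()
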