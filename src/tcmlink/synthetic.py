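"""Synthetic data with planted structure for end-to-end testing.

Emulates the statistical structure of the real inputs without any download:

* replicated treated/vehicle log2 expression with planted differentially
  expressed genes at a controlled effect size (random up/down sign per gene),
* a GWAS-catalog-dialect association table plus trait->MeSH mapping whose
  aggregation reproduces known disease gene sets,
* a sparse scored PPI edge list in the STRING links dialect.

Selected compound-disease pairs are "planted": the compound signature and the
disease gene set intersect in exactly the configured number of genes, so the
downstream permutation test has known positives; every other pair's overlap
arises by chance, so its p-values behave like the null.

Four independent RNG streams (ground truth, expression, catalog, PPI) are
derived from the master seed, so changing one generator's parameters does not
perturb the others; a fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import substream

# substream indices per artifact
_STREAM_TRUTH, _STREAM_EXPR, _STREAM_CATALOG, _STREAM_PPI = 0, 1, 2, 3

#: default planted pairs: first five compounds x first five diseases, overlap 12
_DEFAULT_N_PLANTED = 5
_DEFAULT_PLANTED_OVERLAP = 12


@dataclass
class SyntheticConfig:
    """Stated world for the generator.

    Defaults describe a desk-scale analogue of the real study: a 2,000-gene
    universe (paper-scale would be 20,462), 20 compounds profiled in duplicate
    against duplicate vehicle controls, 30 diseases, five planted
    compound-disease pairs with overlap 12, a 2-fold planted effect
    (de_log2_effect=1.0) and 0.15 log2 units of Gaussian noise. Signature and
    disease set sizes (40-80 and 25-50 genes) keep the background overlap of a
    non-planted pair at a mean of at most ~2 genes (sd ~1.4), so a planted
    overlap of 12 sits far in the background hypergeometric tail.
    """

    n_genes: int = 2_000
    max_probes_per_gene: int = 2
    n_compounds: int = 20
    n_replicates: int = 2
    n_vehicle_replicates: int = 2
    n_diseases: int = 30
    genes_per_disease: tuple[int, int] = (25, 50)
    signature_size: tuple[int, int] = (40, 80)
    planted_pairs: list[tuple[str, str, int]] | None = None
    de_log2_effect: float = 1.0
    noise_sd: float = 0.15
    ppi_density: float = 0.01
    ppi_highconf_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "max_probes_per_gene", "n_compounds", "n_replicates",
                     "n_vehicle_replicates", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("genes_per_disease", "signature_size"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a 1 <= lo <= hi range")
        if self.signature_size[1] > self.n_genes:
            raise ValueError("signature_size exceeds the gene universe")
        if self.genes_per_disease[1] > self.n_genes:
            raise ValueError("genes_per_disease exceeds the gene universe")
        if self.de_log2_effect <= math.log2(1.5):
            raise ValueError("de_log2_effect must exceed log2(1.5) to be callable")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.ppi_density < 1:
            raise ValueError("ppi_density must be in (0, 1)")
        if not 0 <= self.ppi_highconf_fraction <= 1:
            raise ValueError("ppi_highconf_fraction must be in [0, 1]")
        if self.planted_pairs is None:
            k = min(_DEFAULT_N_PLANTED, self.n_compounds, self.n_diseases)
            self.planted_pairs = [
                (self.compound_ids[i], self.disease_ids[i], _DEFAULT_PLANTED_OVERLAP)
                for i in range(k)
            ]
        compounds = set(self.compound_ids)
        diseases = set(self.disease_ids)
        for compound, disease, count in self.planted_pairs:
            if compound not in compounds or disease not in diseases:
                raise ValueError(f"planted pair ({compound}, {disease}) names unknown ids")
            if count < 1:
                raise ValueError("planted overlap_count must be >= 1")
            if count > min(self.signature_size[0], self.genes_per_disease[0]):
                raise ValueError(
                    "planted overlap_count exceeds the minimum signature/disease size"
                )

    # deterministic identifier schemes --------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def compound_ids(self) -> list[str]:
        return [f"TCM{i + 1:03d}" for i in range(self.n_compounds)]

    @property
    def disease_ids(self) -> list[str]:
        # unique level-3 MeSH Disease [C] tree numbers
        return [
            f"C{(i % 98) + 1:02d}.{100 + i // 98:03d}.100" for i in range(self.n_diseases)
        ]


@dataclass
class GroundTruth:
    """Planted structure: what the pipeline should recover."""

    planted_pairs: set[tuple[str, str]]
    planted_overlaps: dict[tuple[str, str], int]
    planted_signatures: dict[str, frozenset[str]]
    planted_signs: dict[str, dict[str, int]]  # compound -> gene -> +1 (up) / -1 (down)
    planted_disease_sets: dict[str, frozenset[str]]

    def to_json(self, path) -> None:
        payload = {
            "planted_pairs": sorted(list(p) for p in self.planted_pairs),
            "planted_overlaps": {f"{c}|{d}": k for (c, d), k in sorted(self.planted_overlaps.items())},
            "planted_signatures": {c: sorted(g) for c, g in sorted(self.planted_signatures.items())},
            "planted_signs": {c: dict(sorted(s.items())) for c, s in sorted(self.planted_signs.items())},
            "planted_disease_sets": {d: sorted(g) for d, g in sorted(self.planted_disease_sets.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def generate_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw planted signatures and disease gene sets honoring exact overlaps.

    Each planted pair gets a dedicated reserved block of ``overlap_count``
    genes present in both its signature and its disease set. Signature fills
    are drawn from the unreserved universe (so one pair's block never leaks
    into another signature); disease fills are drawn from the whole universe
    minus only the signatures of that disease's planted compounds, which keeps
    the planted intersection exact while leaving non-planted disease sets
    uniform draws — non-planted pairs overlap only by chance, matching the
    permutation null.
    """
    rng = substream(config.seed, _STREAM_TRUTH)
    genes = np.array(config.gene_ids)
    total_reserved = sum(k for _, _, k in config.planted_pairs)
    if total_reserved > config.n_genes // 2:
        raise ValueError("planted blocks would reserve more than half the universe")
    reserved = rng.choice(config.n_genes, size=total_reserved, replace=False)
    free_mask = np.ones(config.n_genes, dtype=bool)
    free_mask[reserved] = False
    free = np.flatnonzero(free_mask)

    blocks: dict[tuple[str, str], np.ndarray] = {}
    offset = 0
    for compound, disease, count in config.planted_pairs:
        blocks[(compound, disease)] = reserved[offset:offset + count]
        offset += count

    sig_blocks: dict[str, list[np.ndarray]] = {c: [] for c in config.compound_ids}
    dis_blocks: dict[str, list[np.ndarray]] = {d: [] for d in config.disease_ids}
    dis_partners: dict[str, list[str]] = {d: [] for d in config.disease_ids}
    for (compound, disease), block in blocks.items():
        sig_blocks[compound].append(block)
        dis_blocks[disease].append(block)
        dis_partners[disease].append(compound)

    signatures: dict[str, frozenset[str]] = {}
    signature_idx: dict[str, set[int]] = {}
    for compound in config.compound_ids:
        size = int(rng.integers(config.signature_size[0], config.signature_size[1] + 1))
        planted = np.concatenate(sig_blocks[compound]) if sig_blocks[compound] else np.empty(0, int)
        n_fill = max(0, size - len(planted))
        fill = rng.choice(free, size=n_fill, replace=False)
        idx = set(planted.tolist()) | set(fill.tolist())
        signature_idx[compound] = idx
        signatures[compound] = frozenset(genes[sorted(idx)])

    disease_sets: dict[str, frozenset[str]] = {}
    all_idx = np.arange(config.n_genes)
    for disease in config.disease_ids:
        size = int(rng.integers(config.genes_per_disease[0], config.genes_per_disease[1] + 1))
        planted = np.concatenate(dis_blocks[disease]) if dis_blocks[disease] else np.empty(0, int)
        # excluding exactly the partner signatures keeps the planted overlap
        # exact while leaving non-planted disease sets uniform over the
        # whole universe (so non-planted pairs follow the permutation null)
        exclude: set[int] = set()
        for compound in dis_partners[disease]:
            exclude |= signature_idx[compound]
        if exclude:
            pool = np.array([i for i in all_idx if i not in exclude], dtype=int)
        else:
            pool = all_idx
        n_fill = max(0, size - len(planted))
        fill = rng.choice(pool, size=n_fill, replace=False)
        idx = sorted(set(planted.tolist()) | set(fill.tolist()))
        disease_sets[disease] = frozenset(genes[idx])

    signs = {
        c: {g: int(rng.choice([-1, 1])) for g in sorted(signatures[c])}
        for c in config.compound_ids
    }
    return GroundTruth(
        planted_pairs={(c, d) for c, d, _ in config.planted_pairs},
        planted_overlaps={(c, d): k for c, d, k in config.planted_pairs},
        planted_signatures=signatures,
        planted_signs=signs,
        planted_disease_sets=disease_sets,
    )


def generate_expression(
    config: SyntheticConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Probes x samples log2 matrix, probe->gene map, and sample annotation.

    Per-gene baselines are Uniform(4, 12) on the log2 scale (normalized
    microarray range); each gene gets 1..max_probes_per_gene probes with a
    fixed negative offset (so the max-collapse rule is exercised); vehicle
    samples are baseline + noise; each compound's planted signature genes are
    shifted by +-de_log2_effect with the sign recorded in the ground truth.
    """
    if truth is None:
        truth = generate_truth(config)
    rng = substream(config.seed, _STREAM_EXPR)
    genes = config.gene_ids

    baseline = rng.uniform(4.0, 12.0, size=config.n_genes)
    n_probes = rng.integers(1, config.max_probes_per_gene + 1, size=config.n_genes)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    probe_offset: list[float] = []
    for gi, count in enumerate(n_probes):
        for j in range(count):
            probe_ids.append(f"{genes[gi]}_at{j + 1}")
            probe_gene_idx.append(gi)
            # first probe sits at the gene baseline; extras are attenuated
            probe_offset.append(0.0 if j == 0 else float(rng.uniform(-1.0, -0.1)))
    probe_gene_idx = np.array(probe_gene_idx)
    probe_base = baseline[probe_gene_idx] + np.array(probe_offset)

    sample_ids: list[str] = []
    ann_rows: list[tuple[str, str, str, int]] = []
    shifts: list[np.ndarray] = []  # per-sample gene-level shift
    zero = np.zeros(config.n_genes)
    for r in range(config.n_vehicle_replicates):
        sid = f"VEH_R{r + 1}"
        sample_ids.append(sid)
        ann_rows.append((sid, "DMSO", "vehicle", r + 1))
        shifts.append(zero)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for compound in config.compound_ids:
        shift = np.zeros(config.n_genes)
        for gene, sign in truth.planted_signs[compound].items():
            shift[gene_pos[gene]] = sign * config.de_log2_effect
        for r in range(config.n_replicates):
            sid = f"{compound}_R{r + 1}"
            sample_ids.append(sid)
            ann_rows.append((sid, compound, "treated", r + 1))
            shifts.append(shift)

    values = probe_base[:, None] + np.stack(shifts, axis=1)[probe_gene_idx, :]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    probe_map = pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": [genes[i] for i in probe_gene_idx]}
    )
    annotation = pd.DataFrame(
        ann_rows, columns=["sample_id", "compound", "role", "replicate"]
    )
    return matrix, probe_map, annotation, truth


def generate_disease_catalog(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS-catalog-dialect association table plus trait->MeSH mapping table.

    Each disease's genes are split across 1-3 traits (all mapping to the same
    level-3 term, sometimes via deeper tree numbers to exercise truncation);
    rows carry up to 5 genes in a comma-joined MAPPED_GENE cell. Distractor
    traits (non-C category, shallow depth, intergenic entries) are included;
    the aggregation drops them, so parsing the outputs reproduces
    ``truth.planted_disease_sets`` exactly when PPI expansion is disabled.
    """
    rng = substream(config.seed, _STREAM_CATALOG)
    catalog_rows = []
    mesh_rows = []
    for d_idx, disease in enumerate(config.disease_ids):
        disease_genes = sorted(truth.planted_disease_sets[disease])
        n_traits = int(rng.integers(1, 4))
        assignment = rng.integers(0, n_traits, size=len(disease_genes))
        # ensure no trait is empty by cycling indices
        for t in range(n_traits):
            if not np.any(assignment == t):
                assignment[t % len(disease_genes)] = t
        for t in range(n_traits):
            trait = f"Trait {disease} v{t + 1}"
            trait_genes = [g for g, a in zip(disease_genes, assignment) if a == t]
            if not trait_genes:
                continue
            # deeper tree numbers half the time; level-3 truncation recovers the id
            if rng.random() < 0.5:
                tree = f"{disease}.{int(rng.integers(100, 1000)):03d}"
            else:
                tree = disease
            mesh_rows.append((trait, f"D{900000 + d_idx * 10 + t:06d}", tree))
            for start in range(0, len(trait_genes), 5):
                chunk = trait_genes[start:start + 5]
                cell = ", ".join(chunk)
                if rng.random() < 0.2:
                    cell = cell + ", intergenic"
                catalog_rows.append(
                    (trait, cell, cell, str(20000000 + len(catalog_rows)))
                )
    # distractors: a non-C trait and a too-shallow C trait
    distractor_genes = ", ".join(config.gene_ids[:3])
    catalog_rows.append(("Synthetic non-disease trait", distractor_genes,
                         distractor_genes, "29999998"))
    mesh_rows.append(("Synthetic non-disease trait", "D999998", "D03.383.129"))
    catalog_rows.append(("Synthetic shallow trait", distractor_genes,
                         distractor_genes, "29999999"))
    mesh_rows.append(("Synthetic shallow trait", "D999999", "C04.588"))

    catalog = pd.DataFrame(
        catalog_rows,
        columns=["DISEASE/TRAIT", "MAPPED_GENE", "REPORTED GENE(S)", "PUBMEDID"],
    )
    mesh = pd.DataFrame(mesh_rows, columns=["trait", "mesh_id", "tree_numbers"])
    return catalog, mesh


def generate_ppi(config: SyntheticConfig) -> pd.DataFrame:
    """Scored undirected edge list in the STRING links dialect.

    Erdos-Renyi G(n_genes, ppi_density); a ``ppi_highconf_fraction`` of edges
    scores above the high-confidence cut (901-999 of 1000), the rest 150-900.
    """
    rng = substream(config.seed, _STREAM_PPI)
    n = config.n_genes
    n_pairs = n * (n - 1) // 2
    m = int(rng.binomial(n_pairs, config.ppi_density))
    chosen = rng.choice(n_pairs, size=m, replace=False)
    chosen.sort()
    # unrank pair index -> (i, j), i < j, row-major over the upper triangle
    i = (n - 2 - np.floor(np.sqrt(-8 * chosen + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (chosen + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2).astype(int)
    genes = np.array(config.gene_ids)
    high = rng.random(m) < config.ppi_highconf_fraction
    scores = np.where(high, rng.integers(901, 1000, size=m), rng.integers(150, 901, size=m))
    return pd.DataFrame(
        {"protein1": genes[i], "protein2": genes[j], "combined_score": scores}
    )


def generate_all(config: SyntheticConfig, outdir) -> GroundTruth:
    """Write every synthetic artifact into ``outdir`` and return the truth.

    Files: expression.tsv, probe_map.tsv, annotation.tsv, gwas_catalog.tsv,
    mesh_map.tsv, ppi_links.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    matrix, probe_map, annotation, _ = generate_expression(config, truth)
    catalog, mesh = generate_disease_catalog(config, truth)
    ppi = generate_ppi(config)

    matrix.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    catalog.to_csv(outdir / "gwas_catalog.tsv", sep="\t", index=False)
    mesh.to_csv(outdir / "mesh_map.tsv", sep="\t", index=False)
    ppi.to_csv(outdir / "ppi_links.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return truth
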