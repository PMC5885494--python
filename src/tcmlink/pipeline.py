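"""End-to-end pipeline: signatures -> disease network -> prioritization.

Everything written here is re-derivable from the emitted artifact files; the
run summary contains no state that lives only in memory, and artifacts are
byte-identical across reruns with the same config and seed (wall-clock time is
logged, not written into artifacts).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import disease as disease_mod
from . import signatures as sig_mod
from .prioritize import (
    DEFAULT_N_PERMUTATIONS,
    DEFAULT_Q_THRESHOLD,
    CompoundDiseaseModel,
    CompoundDiseaseResults,
    as_universe,
    permutation_test,
    z_score,
)
from ._util import pair_rng, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for one reproducible run."""

    expression: str
    probe_map: str
    annotation: str
    catalog: str
    mesh_map: str
    outdir: str
    ppi: str | None = None
    fold_change: float = sig_mod.DEFAULT_FOLD_CHANGE
    score_threshold: float = disease_mod.DEFAULT_SCORE_THRESHOLD
    max_added: int = disease_mod.DEFAULT_MAX_ADDED
    universe_size: int | None = None
    n_perm: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0
    q_threshold: float = DEFAULT_Q_THRESHOLD
    min_overlap: int = 0
    pseudocount: bool = False
    include_reported: bool = False

    def __post_init__(self) -> None:
        required = {
            "expression": self.expression,
            "probe_map": self.probe_map,
            "annotation": self.annotation,
            "catalog": self.catalog,
            "mesh_map": self.mesh_map,
        }
        if self.ppi is not None:
            required["ppi"] = self.ppi
        for name, path in required.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunSummary:
    """Table-1-style counts for both networks plus the test outcome."""

    tcm_network: dict
    disease_network: dict
    n_pairs_tested: int
    n_significant: int
    q_threshold: float
    universe_size: int
    n_perm: int
    seed: int
    elapsed_seconds: float = field(repr=False, default=0.0)

    def to_text(self) -> str:
        t, d = self.tcm_network, self.disease_network
        lines = [
            "Run summary",
            "===========",
            "",
            "Compound-target gene network",
            f"  compounds:                {t['n_compounds']}",
            f"  target genes:             {t['n_target_genes']}",
            f"  mean genes per compound:  {t['mean_targets_per_compound']}",
            f"  compound-gene edges:      {t['n_interactions']}",
            "",
            "GWAS disease-gene network",
            f"  diseases:                 {d.n_diseases}",
            f"  disease genes:            {d.n_genes}",
            f"  mean genes per disease:   {d.mean_genes_per_disease}",
            f"  disease-gene edges:       {d.n_interactions}",
            "",
            "Prioritization",
            f"  universe size N:          {self.universe_size}",
            f"  permutations per pair:    {self.n_perm}",
            f"  seed:                     {self.seed}",
            f"  pairs tested:             {self.n_pairs_tested}",
            f"  significant (q < {self.q_threshold:g}):   {self.n_significant}",
        ]
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> tuple[RunSummary, CompoundDiseaseResults]:
    """Execute all stages and write every artifact into ``config.outdir``."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage signatures: reading expression inputs")
    matrix = sig_mod.read_expression(config.expression)
    probe_map = sig_mod.read_probe_map(config.probe_map)
    annotation = sig_mod.read_annotation(config.annotation)
    signatures = sig_mod.build_signature_set(matrix, probe_map, annotation,
                                            threshold=config.fold_change)
    signatures.to_gmt(outdir / "signatures.gmt")
    signatures.to_edge_tsv(outdir / "tcm_gene_edges.tsv")
    tcm_summary = signatures.summary()
    logger.info("stage signatures: %s", tcm_summary)

    logger.info("stage disease-net: parsing catalog")
    records = disease_mod.parse_gwas_catalog(config.catalog,
                                             include_reported=config.include_reported)
    mapping = disease_mod.read_mesh_mapping(config.mesh_map)
    network = disease_mod.aggregate_disease_genes(records, mapping)
    if config.ppi is not None:
        edges = disease_mod.read_string_links(config.ppi)
        network = disease_mod.expand_with_ppi(network, edges,
                                              score_threshold=config.score_threshold,
                                              max_added=config.max_added)
    network.to_edge_tsv(outdir / "disease_gene_edges.tsv")
    network.to_sif(outdir / "disease_gene_network.sif")
    disease_summary = network.summary()
    logger.info("stage disease-net: %s", disease_summary)

    logger.info("stage prioritize: %d x %d pairs", len(signatures.compounds),
                len(network.diseases))
    universe = config.universe_size if config.universe_size else signatures.universe
    model = CompoundDiseaseModel(signatures, network, universe=universe,
                                 min_overlap=config.min_overlap)
    results = model.fit(n_perm=config.n_perm, seed=config.seed,
                        q_threshold=config.q_threshold,
                        pseudocount=config.pseudocount)
    results.to_tsv(outdir / "pair_results.tsv")
    results.to_sif(outdir / "significant_pairs.sif")
    results.heatmap_matrix().to_csv(outdir / "z_matrix.tsv", sep="\t",
                                    float_format="%.6g")

    summary = RunSummary(
        tcm_network=tcm_summary,
        disease_network=disease_summary,
        n_pairs_tested=results.n_tested,
        n_significant=len(results.significant),
        q_threshold=config.q_threshold,
        universe_size=model.universe.size,
        n_perm=config.n_perm,
        seed=config.seed,
        elapsed_seconds=time.perf_counter() - t0,
    )
    (outdir / "run_summary.txt").write_text(summary.to_text())
    config.to_yaml(outdir / "effective_config.yaml")
    logger.info("pipeline finished in %.1f s", summary.elapsed_seconds)
    return summary, results


def export_heatmap_matrix(results, path=None) -> pd.DataFrame:
    """Compounds x diseases matrix of Z-scores; NaN cells export as empty."""
    if isinstance(results, CompoundDiseaseResults):
        matrix = results.heatmap_matrix()
    else:  # a list of PairResult
        frame = pd.DataFrame(
            [(r.compound, r.disease_id, r.z) for r in results],
            columns=["compound", "disease_id", "z"],
        )
        if frame.empty:
            raise ValueError("no results to export")
        matrix = frame.pivot(index="compound", columns="disease_id", values="z")
    if path is not None:
        matrix.to_csv(path, sep="\t", float_format="%.6g")
    return matrix


def query_disease_genes(
    genes,
    signatures: sig_mod.SignatureSet,
    universe=None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank every compound against a submitted disease gene list.

    The interactive query mode: the submitted set plays the disease role in
    the permutation test of each compound signature; compounds are returned
    sorted by p then Z (descending).
    """
    genes = [normalize_symbol(g) for g in genes]
    if not genes:
        raise ValueError("submitted gene list is empty")
    spec = as_universe(universe if universe is not None else signatures.universe)
    query_set = spec.restrict(genes)
    if not query_set:
        raise ValueError(
            "none of the submitted genes are in the measured universe; "
            "check symbols against the expression data"
        )
    rows = []
    for compound in signatures.compounds:
        targets = spec.restrict(signatures.targets(compound))
        g_obs = len(targets & query_set)
        null = permutation_test(
            K=len(targets), n=len(query_set), g_obs=g_obs, universe=spec,
            n_perm=n_perm, rng=pair_rng(seed, compound, "__query__"),
        )
        rows.append({
            "compound": compound, "K": len(targets), "n": len(query_set),
            "overlap": g_obs, "p": null.p_value,
            "z": z_score(g_obs, null.mu, null.sigma),
        })
    frame = pd.DataFrame(rows)
    zkey = -frame["z"].fillna(float("-inf"))
    frame = (frame.assign(_zkey=zkey)
             .sort_values(["p", "_zkey", "compound"], kind="mergesort")
             .drop(columns="_zkey").reset_index(drop=True))
    return frame
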