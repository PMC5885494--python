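"""Compound expression signatures (the compound-target gene network).

A normalized (log2-scale, RMA-convention) expression matrix is reduced to one
up/down differentially expressed gene set per compound:

1. probe sets for the same gene are collapsed by taking the per-sample maximum,
2. treated replicates are averaged on the log2 scale (vehicle samples are
   averaged into a single vehicle column),
3. a gene enters the "up" set when its linear fold change versus vehicle,
   FC = 2**(treated - vehicle), is >= the threshold (default 1.5), and the
   "down" set when FC <= 1/threshold.

The union up | down is treated as the compound's target gene set and forms one
side of the bipartite compound-gene network scored downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import mean_per_entity, normalize_symbol

logger = logging.getLogger(__name__)

#: Reserved condition label for the pooled vehicle column.
VEHICLE_LABEL = "VEHICLE"

DEFAULT_FOLD_CHANGE = 1.5


# ---------------------------------------------------------------------------
# readers for the TSV dialects emitted by tcmlink.synthetic


def read_expression(path) -> pd.DataFrame:
    """Read a probes x samples TSV of log2 intensities (first column = probe id)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        raise ValueError("duplicate probe identifiers in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-numeric or non-finite values")
    return matrix


def read_probe_map(path) -> pd.DataFrame:
    """Read a probe_id / gene_symbol TSV; symbols are uppercased."""
    probe_map = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in probe_map.columns:
            raise ValueError(f"probe map is missing required column {col!r}")
    probe_map["gene_symbol"] = probe_map["gene_symbol"].map(normalize_symbol)
    return probe_map


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV (sample_id, compound, role, replicate)."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compound": str, "role": str})
    for col in ("sample_id", "compound", "role"):
        if col not in ann.columns:
            raise ValueError(f"annotation is missing required column {col!r}")
    bad = set(ann["role"]) - {"treated", "vehicle"}
    if bad:
        raise ValueError(f"annotation roles must be treated|vehicle, got {sorted(bad)}")
    return ann


# ---------------------------------------------------------------------------
# core operations


def collapse_probes(matrix: pd.DataFrame, probe_map) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by the per-sample maximum.

    Probes without a gene mapping are dropped; probes mapped to more than one
    distinct gene are dropped as well (rather than duplicated) to avoid double
    counting.

    Parameters
    ----------
    matrix : DataFrame, probes x samples.
    probe_map : mapping, Series, or DataFrame with probe_id/gene_symbol columns.
    """
    if isinstance(probe_map, pd.DataFrame):
        pm = probe_map.set_index("probe_id")["gene_symbol"]
    elif isinstance(probe_map, pd.Series):
        pm = probe_map
    else:
        pm = pd.Series(dict(probe_map))
    pm = pm.map(normalize_symbol)

    # drop probes claimed by more than one gene
    multi = pm.index[pm.index.duplicated(keep=False)]
    if len(multi):
        ambiguous = pm.loc[multi].groupby(level=0).nunique()
        drop = set(ambiguous.index[ambiguous > 1])
        if drop:
            logger.info("dropping %d probes mapped to multiple genes", len(drop))
            pm = pm[~pm.index.isin(drop)]
        pm = pm[~pm.index.duplicated()]

    keep = matrix.index.intersection(pm.index)
    if keep.empty:
        raise ValueError("no probe in the expression matrix has a gene mapping")
    collapsed = matrix.loc[keep].groupby(pm.loc[keep]).max()
    collapsed.index.name = "gene"
    return collapsed


def average_replicates(gene_matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples per condition on the log2 scale.

    Returns one column per compound plus a single pooled ``VEHICLE`` column.
    """
    missing = set(annotation["sample_id"]) - set(gene_matrix.columns)
    if missing:
        raise ValueError(f"annotated samples absent from matrix: {sorted(missing)[:5]}")
    if not (annotation["role"] == "vehicle").any():
        raise ValueError("annotation contains no vehicle sample")

    labels = annotation.apply(
        lambda r: VEHICLE_LABEL if r["role"] == "vehicle" else r["compound"], axis=1
    )
    if (labels[annotation["role"] == "treated"] == VEHICLE_LABEL).any():
        raise ValueError(f"compound label {VEHICLE_LABEL!r} is reserved")
    by_condition: dict[str, list[str]] = {}
    for sample, label in zip(annotation["sample_id"], labels):
        by_condition.setdefault(label, []).append(sample)
    for label, samples in by_condition.items():
        if not samples:  # pragma: no cover - defensive
            raise ValueError(f"condition {label!r} has zero samples")
    out = pd.DataFrame(
        {label: gene_matrix[samples].mean(axis=1) for label, samples in sorted(by_condition.items())}
    )
    return out


def call_signature(
    condition_matrix: pd.DataFrame,
    compound: str,
    threshold: float = DEFAULT_FOLD_CHANGE,
) -> tuple[frozenset[str], frozenset[str]]:
    """Call up/down gene sets for one compound by fold change versus vehicle.

    FC = 2**(treated_log2 - vehicle_log2); up iff FC >= threshold, down iff
    FC <= 1/threshold (both inclusive). Comparison is done on the log2
    difference, which is exactly equivalent and avoids exponentiation error.
    """
    if threshold <= 1:
        raise ValueError(f"fold-change threshold must exceed 1, got {threshold}")
    if compound not in condition_matrix.columns:
        raise KeyError(f"compound {compound!r} not present in condition matrix")
    if VEHICLE_LABEL not in condition_matrix.columns:
        raise ValueError("condition matrix has no vehicle column")
    diff = condition_matrix[compound] - condition_matrix[VEHICLE_LABEL]
    cut = math.log2(threshold)
    up = frozenset(diff.index[diff >= cut])
    down = frozenset(diff.index[diff <= -cut])
    return up, down


@dataclass
class SignatureSet:
    """Per-compound up/down differentially expressed gene sets.

    The bipartite compound-target network: one edge per (compound, gene) with
    gene in up | down.
    """

    signatures: dict[str, tuple[frozenset[str], frozenset[str]]]
    universe: frozenset[str]
    fold_change_threshold: float = DEFAULT_FOLD_CHANGE

    def __post_init__(self) -> None:
        for compound, (up, down) in self.signatures.items():
            if up & down:
                raise ValueError(f"up/down sets overlap for compound {compound!r}")

    @property
    def compounds(self) -> list[str]:
        return sorted(self.signatures)

    def targets(self, compound: str) -> frozenset[str]:
        up, down = self.signatures[compound]
        return up | down

    def summary(self) -> dict[str, int]:
        """Network-level counts: compounds, distinct target genes, interactions,
        and the mean target-set size per compound (rounded half away from zero)."""
        all_targets: set[str] = set()
        interactions = 0
        for compound in self.signatures:
            t = self.targets(compound)
            all_targets |= set(t)
            interactions += len(t)
        n = len(self.signatures)
        return {
            "n_compounds": n,
            "n_target_genes": len(all_targets),
            "n_interactions": interactions,
            "mean_targets_per_compound": mean_per_entity(interactions, n) if n else 0,
        }

    # -- serialization ------------------------------------------------------

    def to_gmt(self, path) -> None:
        """Write one GMT line per compound_UP / compound_DOWN set."""
        with open(path, "w") as fh:
            for compound in self.compounds:
                up, down = self.signatures[compound]
                for suffix, genes in (("UP", up), ("DOWN", down)):
                    fields = [f"{compound}_{suffix}", compound, *sorted(genes)]
                    fh.write("\t".join(fields) + "\n")

    def to_edge_tsv(self, path) -> None:
        """Write the bipartite compound-gene edge list (compound, gene)."""
        with open(path, "w") as fh:
            fh.write("compound\tgene\n")
            for compound in self.compounds:
                for gene in sorted(self.targets(compound)):
                    fh.write(f"{compound}\t{gene}\n")


def read_gmt(path, fold_change_threshold: float = DEFAULT_FOLD_CHANGE) -> SignatureSet:
    """Read a SignatureSet back from the GMT written by :meth:`SignatureSet.to_gmt`.

    The measured universe is not stored in GMT; the reconstructed universe is
    the union of all signature genes (callers scoring against a larger universe
    should pass it explicitly downstream).
    """
    ups: dict[str, frozenset[str]] = {}
    downs: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            name, _desc, *genes = fields
            genes = frozenset(normalize_symbol(g) for g in genes if g)
            if name.endswith("_UP"):
                ups[name[:-3]] = genes
            elif name.endswith("_DOWN"):
                downs[name[:-5]] = genes
            else:
                raise ValueError(f"GMT set name {name!r} lacks _UP/_DOWN suffix")
    compounds = sorted(set(ups) | set(downs))
    signatures = {
        c: (ups.get(c, frozenset()), downs.get(c, frozenset())) for c in compounds
    }
    universe = frozenset().union(*(u | d for u, d in signatures.values())) if signatures else frozenset()
    return SignatureSet(signatures, universe, fold_change_threshold)


def build_signature_set(
    matrix: pd.DataFrame,
    probe_map,
    annotation: pd.DataFrame,
    threshold: float = DEFAULT_FOLD_CHANGE,
) -> SignatureSet:
    """Collapse -> average -> call, for every compound in the annotation."""
    gene_matrix = collapse_probes(matrix, probe_map)
    condition_matrix = average_replicates(gene_matrix, annotation)
    compounds = sorted(c for c in condition_matrix.columns if c != VEHICLE_LABEL)
    signatures = {c: call_signature(condition_matrix, c, threshold) for c in compounds}
    universe = frozenset(gene_matrix.index)
    return SignatureSet(signatures, universe, threshold)
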