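"""Permutation-based prioritization of compound-disease pairs.

For a compound with target set of size K and a disease with n genes, both
inside a gene universe of size N, the observed overlap G is compared with a
Monte-Carlo null in which the disease gene set is replaced by an equal-sized
uniform random draw (without replacement) from the universe:

    P = #{permutations with null overlap > G} / #permutations        (strict)
    Z = (G - mu) / sigma

where mu and sigma are the sample mean and sample standard deviation (ddof=1)
of the null overlaps. Nominal p-values are Benjamini-Hochberg adjusted across
all tested pairs; pairs with q < 0.2 are flagged significant.

The null overlap of a uniform n-subset with a fixed K-set is distributed
Hypergeometric(N, K, n), so the default sampler draws the null overlap counts
directly with numpy's hypergeometric generator — a Monte-Carlo simulation that
is distributionally identical to materializing each permuted gene set, at O(1)
per permutation. ``method="subsets"`` materializes the permuted sets instead
(slow; used to validate the fast path). The exact closed forms are available
separately in :func:`hypergeometric_oracle` for validation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import pair_rng
from .disease import DiseaseGeneNetwork
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 100_000
DEFAULT_Q_THRESHOLD = 0.2
#: genome-wide universe size used when scoring against a fixed genome scale
GENOME_WIDE_SIZE = 20_462


@dataclass(frozen=True)
class UniverseSpec:
    """The gene universe permutations draw from.

    ``genes`` may be None when only the size is known (fixed genome-scale
    universe); gene sets are then assumed to live inside it.
    """

    size: int
    genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("universe size must be positive")
        if self.genes is not None and len(self.genes) != self.size:
            raise ValueError("universe size does not match the gene set")

    def restrict(self, gene_set: Iterable[str]) -> frozenset[str]:
        gene_set = frozenset(gene_set)
        if self.genes is None:
            return gene_set
        return gene_set & self.genes


def as_universe(universe) -> UniverseSpec:
    """Coerce an int, a gene collection, or a UniverseSpec into a UniverseSpec."""
    if isinstance(universe, UniverseSpec):
        return universe
    if isinstance(universe, (int, np.integer)):
        return UniverseSpec(size=int(universe))
    genes = frozenset(universe)
    return UniverseSpec(size=len(genes), genes=genes)


def overlap_count(targets: Iterable[str], disease_genes: Iterable[str], universe) -> int:
    """|targets ∩ disease_genes ∩ universe|."""
    spec = as_universe(universe)
    return len(spec.restrict(targets) & spec.restrict(disease_genes))


@dataclass(frozen=True)
class PermutationNull:
    """Monte-Carlo null for one compound-disease pair."""

    n_permutations: int
    g_obs: int
    mu: float
    sigma: float
    exceed_count: int
    tie_count: int
    seed: int | None = None

    @property
    def p_value(self) -> float:
        """Strict-exceedance nominal p (can be exactly 0)."""
        return self.exceed_count / self.n_permutations

    @property
    def p_pseudocount(self) -> float:
        """(exceed + 1)/(n_perm + 1), for users who need a nonzero p."""
        return (self.exceed_count + 1) / (self.n_permutations + 1)

    @property
    def z(self) -> float:
        return z_score(self.g_obs, self.mu, self.sigma)


def _sample_null_overlaps(
    K: int, n: int, N: int, n_perm: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    if method == "counts":
        if K == 0 or n == 0:
            return np.zeros(n_perm, dtype=np.int64)
        return rng.hypergeometric(K, N - K, n, size=n_perm)
    if method == "subsets":
        # literal reading: draw the n-gene set and count members of the target
        # set (genes indexed so targets are 0..K-1); O(N) per permutation
        draws = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            subset = rng.choice(N, size=n, replace=False)
            draws[i] = int((subset < K).sum())
        return draws
    raise ValueError(f"unknown sampling method {method!r}")


def permutation_test(
    K: int,
    n: int,
    g_obs: int,
    universe,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    method: str = "counts",
) -> PermutationNull:
    """Monte-Carlo permutation test of an observed overlap.

    Each permutation draws ``n`` genes uniformly without replacement from the
    universe and counts the overlap with the fixed ``K``-gene target set.
    """
    N = as_universe(universe).size
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K={K}, n={n} <= N={N}")
    if not 0 <= g_obs <= min(K, n):
        raise ValueError(f"g_obs={g_obs} outside [0, min(K={K}, n={n})]")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = _sample_null_overlaps(K, n, N, n_perm, rng, method)
    return PermutationNull(
        n_permutations=n_perm,
        g_obs=int(g_obs),
        mu=float(draws.mean()),
        sigma=float(draws.std(ddof=1)) if n_perm > 1 else 0.0,
        exceed_count=int((draws > g_obs).sum()),
        tie_count=int((draws == g_obs).sum()),
        seed=seed,
    )


def hypergeometric_oracle(K: int, n: int, g_obs: int, N: int) -> tuple[float, float, float]:
    """Exact (tail P(X > g_obs), mean, sd) of the Hypergeometric(N, K, n) null.

    Validation-only closed form for the sampling scheme of the permutation
    test; mean = nK/N, sd = sqrt(nK(N-K)(N-n) / (N^2 (N-1))).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K={K}, n={n} <= N={N}")
    dist = stats.hypergeom(N, K, n)
    with np.errstate(divide="ignore", invalid="ignore"):  # scipy moment code
        return float(dist.sf(g_obs)), float(dist.mean()), float(dist.std())


def z_score(g_obs: float, mu: float, sigma: float) -> float:
    """(g_obs - mu)/sigma; NaN (undefined) when sigma == 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return float("nan")
    return (g_obs - mu) / sigma


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results


@dataclass(frozen=True)
class PairResult:
    """One scored compound-disease pair."""

    compound: str
    disease_id: str
    disease_label: str
    K: int
    n: int
    overlap: int
    p: float
    z: float
    q: float
    significant: bool


class CompoundDiseaseModel:
    """Permutation-overlap model connecting compound signatures to disease genes.

    Parameters
    ----------
    signatures : SignatureSet or mapping compound -> gene set
        Compound target sets (up | down differentially expressed genes).
    diseases : DiseaseGeneNetwork or mapping disease id -> gene set
        Disease gene sets (optionally PPI-expanded).
    universe : UniverseSpec, gene collection, or int, optional
        Universe the permutations draw from. Defaults to the measured-gene
        universe of the SignatureSet; pass an int (e.g. 20462) to emulate a
        fixed genome-wide scale.
    min_overlap : int
        Pairs with observed overlap below this are not tested (and do not
        enter the BH correction).
    """

    def __init__(self, signatures, diseases, universe=None, min_overlap: int = 0):
        if isinstance(signatures, SignatureSet):
            self.targets = {c: signatures.targets(c) for c in signatures.compounds}
            default_universe = signatures.universe
        else:
            self.targets = {c: frozenset(g) for c, g in dict(signatures).items()}
            default_universe = frozenset().union(*self.targets.values()) if self.targets else frozenset()
        if isinstance(diseases, DiseaseGeneNetwork):
            self.disease_sets = {d: frozenset(g) for d, g in diseases.diseases.items()}
            self.disease_labels = dict(diseases.labels)
        else:
            self.disease_sets = {d: frozenset(g) for d, g in dict(diseases).items()}
            self.disease_labels = {d: d for d in self.disease_sets}
        if not self.targets or not self.disease_sets:
            raise ValueError("signatures and diseases must both be non-empty")
        self.universe = as_universe(universe if universe is not None else default_universe)
        if self.universe.size == 0:
            raise ValueError("empty gene universe")
        self.min_overlap = int(min_overlap)

    def fit(
        self,
        n_perm: int = DEFAULT_N_PERMUTATIONS,
        seed: int = 0,
        q_threshold: float = DEFAULT_Q_THRESHOLD,
        pseudocount: bool = False,
        method: str = "counts",
    ) -> "CompoundDiseaseResults":
        """Score every pair and BH-adjust jointly across all tested pairs.

        Each pair uses an independent RNG substream keyed by
        (seed, compound, disease), so results do not depend on iteration order.
        """
        rows = []
        n_dropped_genes = 0
        for compound in sorted(self.targets):
            targets = self.universe.restrict(self.targets[compound])
            n_dropped_genes += len(self.targets[compound]) - len(targets)
            for disease_id in sorted(self.disease_sets):
                disease_genes = self.universe.restrict(self.disease_sets[disease_id])
                g_obs = len(targets & disease_genes)
                if g_obs < self.min_overlap:
                    continue
                null = permutation_test(
                    K=len(targets),
                    n=len(disease_genes),
                    g_obs=g_obs,
                    universe=self.universe,
                    n_perm=n_perm,
                    rng=pair_rng(seed, compound, disease_id),
                    method=method,
                )
                rows.append(
                    {
                        "compound": compound,
                        "disease_id": disease_id,
                        "disease_label": self.disease_labels.get(disease_id, disease_id),
                        "K": len(targets),
                        "n": len(disease_genes),
                        "overlap": g_obs,
                        "p": null.p_pseudocount if pseudocount else null.p_value,
                        "z": null.z,
                        "mu": null.mu,
                        "sigma": null.sigma,
                        "exceed": null.exceed_count,
                        "ties": null.tie_count,
                    }
                )
        if n_dropped_genes:
            logger.info("%d signature genes fell outside the universe", n_dropped_genes)
        frame = pd.DataFrame(rows)
        if frame.empty:
            raise ValueError("no pair passed the min_overlap filter")
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        # sigma=0 pairs have an undefined Z (constant null, e.g. empty target
        # set): they are excluded from significance and ranked last
        degenerate = frame["sigma"] == 0
        frame["significant"] = (frame["q"] < q_threshold) & ~degenerate
        z_key = frame["z"].fillna(-np.inf)
        frame = (
            frame.assign(_zkey=-z_key, _degen=degenerate)
            .sort_values(["_degen", "q", "p", "_zkey", "compound", "disease_id"],
                         kind="mergesort")
            .drop(columns=["_zkey", "_degen"])
            .reset_index(drop=True)
        )
        return CompoundDiseaseResults(
            frame,
            model=self,
            n_perm=n_perm,
            seed=seed,
            q_threshold=q_threshold,
            pseudocount=pseudocount,
        )


class CompoundDiseaseResults:
    """Fitted pair table with ranking, export and plotting helpers."""

    def __init__(self, frame, model, n_perm, seed, q_threshold, pseudocount):
        self.frame = frame
        self.model = model
        self.n_perm = n_perm
        self.seed = seed
        self.q_threshold = q_threshold
        self.pseudocount = pseudocount

    @property
    def n_tested(self) -> int:
        return len(self.frame)

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def pair_results(self) -> list[PairResult]:
        cols = ["compound", "disease_id", "disease_label", "K", "n", "overlap",
                "p", "z", "q", "significant"]
        return [PairResult(*row) for row in self.frame[cols].itertuples(index=False)]

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Compound-disease permutation overlap test",
            "=" * 41,
            f"universe size N:        {self.model.universe.size}",
            f"compounds:              {len(self.model.targets)}",
            f"diseases:               {len(self.model.disease_sets)}",
            f"pairs tested:           {self.n_tested}",
            f"permutations per pair:  {self.n_perm}",
            f"significant (q < {self.q_threshold:g}): {len(sig)}",
        ]
        if len(sig):
            lines.append("")
            lines.append("top pairs:")
            head = sig.head(10)[["compound", "disease_id", "overlap", "p", "z", "q"]]
            lines.append(head.to_string(index=False))
        return "\n".join(lines)

    # -- exports ------------------------------------------------------------

    _TSV_COLUMNS = ["compound", "disease_id", "disease_label", "K", "n",
                    "overlap", "p", "z", "q", "significant"]

    def to_tsv(self, path) -> None:
        """Ranked machine-readable pair table."""
        self.frame[self._TSV_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_sif(self, path, relation: str = "connected") -> None:
        """Significant compound-disease edges for Cytoscape import."""
        with open(path, "w") as fh:
            for row in self.significant.itertuples(index=False):
                fh.write(f"{row.compound}\t{relation}\t{row.disease_id}\n")

    def heatmap_matrix(self) -> pd.DataFrame:
        """Compounds x diseases matrix of Z-scores (NaN where undefined/untested)."""
        return self.frame.pivot(index="compound", columns="disease_id", values="z")

    def plot_heatmap(self, ax=None, **imshow_kw):
        """Z-score heatmap of all tested pairs (matplotlib)."""
        import matplotlib.pyplot as plt

        matrix = self.heatmap_matrix()
        if ax is None:
            _fig, ax = plt.subplots(
                figsize=(max(4, 0.3 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0]))
            )
        image = ax.imshow(matrix.to_numpy(), aspect="auto", **imshow_kw)
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
        ax.figure.colorbar(image, ax=ax, label="Z")
        return ax


def prioritize_all(
    signatures,
    diseases,
    universe=None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_overlap: int = 0,
    pseudocount: bool = False,
) -> list[PairResult]:
    """Score every compound-disease pair; functional wrapper around the model."""
    model = CompoundDiseaseModel(signatures, diseases, universe, min_overlap)
    results = model.fit(n_perm=n_perm, seed=seed, q_threshold=q_threshold,
                        pseudocount=pseudocount)
    return results.pair_results()
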