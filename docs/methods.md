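# Methods

## Pipeline overview

`tcmlink` connects two bipartite networks through a permutation statistic:

1. **Compound → target genes** (`tcmlink.signatures`). A probes × samples
   log2 expression matrix is collapsed to gene level (per-sample maximum over
   a gene's probe sets), replicates are averaged per condition on the log2
   scale, vehicle samples are pooled into one column, and a gene joins a
   compound's signature when its linear fold change versus vehicle,
   FC = 2^(treated − vehicle), is ≥ t ("up") or ≤ 1/t ("down"), t = 1.5 by
   default. The union up ∪ down is the compound's target set.
2. **Disease → genes** (`tcmlink.disease`). GWAS catalog rows are parsed
   (`MAPPED_GENE` primary, `REPORTED GENE(S)` optional; cells split on ","
   and " - "; `intergenic` and empty entries dropped; symbols uppercased),
   and each trait's genes are pooled under every level-3 ancestor of its MeSH
   tree numbers within the Disease [C] category. Each disease set can be
   expanded by at most `max_added` (default 100) one-hop PPI neighbors of its
   catalog genes through edges with combined score strictly > 0.9, ranked by
   best edge score to the seed set with lexicographic tie-break so the cap is
   deterministic.
3. **Prioritization** (`tcmlink.prioritize`). Every compound × disease pair
   is scored: observed overlap G inside the universe, strict-exceedance
   permutation p, Z = (G − μ)/σ from the permutation moments, and BH q-values
   computed jointly across all tested pairs; q < 0.2 flags significance.

## Model and assumptions

- **Input scale.** Expression values are assumed log2 (the RMA convention);
  the fold-change comparison is done on log2 differences, which is exactly
  equivalent to the linear-scale rule and avoids exponentiation round-off.
- **Probe collapse before averaging.** Collapse-then-average and
  average-then-collapse differ only when different probes win the per-sample
  maximum in different samples; collapse-first is used, matching the common
  max-probe convention.
- **Dose is ignored**: one signature per compound label, whatever the
  treated concentration; replicates of both doses average together.
- **Null model.** The permutation null replaces the *disease* gene set with a
  uniform draw of the same size from the universe, holding the compound's
  target set fixed. The universe defaults to the measured genes of the
  expression matrix; a fixed genome-wide size (e.g. 20,462) can be supplied
  instead, in which case gene sets are assumed to live inside it. Disease
  genes outside the universe are dropped before testing (counted in the log).
- **Sampling shortcut.** The overlap of a uniform n-subset with a fixed K-set
  is Hypergeometric(N, K, n); the default sampler draws the null overlaps
  from numpy's hypergeometric generator rather than materializing each
  permuted gene set. This is a genuine Monte-Carlo draw with the identical
  law, O(1) per permutation instead of O(N). `method="subsets"` keeps the
  literal draw-and-count reading; a test verifies the two agree, and the
  analytic tail/mean/sd (`hypergeometric_oracle`, used nowhere in the
  pipeline itself) validates both.
- **Strict inequality.** P counts permutations with overlap strictly greater
  than observed, so P can be exactly 0. A `pseudocount` option reports
  (exceed + 1)/(n_perm + 1) instead, default off.
- **σ uses ddof = 1** (sample standard deviation). At 100,000 draws the
  difference from the population form is negligible, but it is pinned for
  reproducibility.
- **Degenerate nulls.** When σ = 0 (empty target set, or a set covering the
  whole universe) Z is undefined; such pairs are reported with Z = NaN,
  excluded from the significance flag, and ranked last.
- **Reproducibility.** Each pair draws from an RNG substream keyed by
  (seed, compound id, disease id) via a stable 64-bit hash, so results are
  independent of iteration order and safe to parallelize. All artifact files
  are byte-identical across reruns with the same config and seed; wall-clock
  time is logged but never written into artifacts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fold_change` | 1.5 | linear fold-change cut for signature membership (inclusive) |
| `score_threshold` | 0.9 | PPI combined score, strict lower bound (900/1000 in STRING files) |
| `max_added` | 100 | cap on PPI-expansion genes per disease |
| `n_perm` | 100,000 | permutations per pair (10,000 in the acceptance run for speed; the MC standard error of p scales as sqrt(p(1−p)/n_perm)) |
| `q_threshold` | 0.2 | BH q-value below which a pair is called significant |
| `min_overlap` | 0 | pairs with smaller observed overlap are not tested (and stay out of the BH family) |
| `universe_size` | measured genes | override to emulate a fixed genome-wide universe |

## The synthetic world

The generator (`tcmlink.synthetic`) emulates the statistical structure the
pipeline assumes, not the raw technology: generation starts at the
normalized-matrix level (no probe-level CEL data, no RMA).

- Per-gene baselines are Uniform(4, 12) log2 units; each gene has 1–2 probes
  (the extras offset downward so the max-collapse rule is exercised); i.i.d.
  Gaussian noise (default sd 0.15 log2 units) is added per probe × sample.
- Each compound's planted signature genes shift by ±`de_log2_effect`
  (default 1.0, i.e. 2-fold), sign random per gene and recorded in the
  ground truth. Treated and vehicle conditions default to duplicates.
- Five compound–disease pairs are planted with an overlap of exactly 12
  genes. Signature sizes (40–80) and disease set sizes (25–50) keep a
  non-planted pair's background overlap at mean ≤ ~2, sd ~1.4 in the
  2,000-gene default universe, so the planted overlap sits ~7 sd into the
  background tail.
- Exactness construction: every planted pair owns a reserved gene block;
  signature fills avoid all reserved blocks, and a disease's fill avoids its
  partner compounds' signatures. Consequently non-planted *diseases* are
  uniform draws from the whole universe — their pairs follow the permutation
  null exactly — while pairs combining a planted disease with a non-partner
  compound are mildly conservative by construction; uniformity checks
  therefore use the pairs whose disease carries no planted signal.
- The GWAS-catalog emulation splits each disease's genes over 1–3 traits
  (rows of ≤ 5 genes, occasional `intergenic` tokens, distractor traits with
  non-C or too-shallow MeSH mappings), and the MeSH table maps traits to the
  disease's level-3 tree number, half the time via a deeper descendant, so
  parsing + aggregation reproduces the planted sets exactly. The PPI
  emulation is an Erdős–Rényi graph with a configurable high-confidence
  score fraction.
- One RNG substream per artifact (truth / expression / catalog / PPI), all
  derived from the master seed: changing one generator's parameters leaves
  the other artifacts untouched, and a fixed seed fixes every output byte.

What a green synthetic run does **not** establish: robustness to microarray
artifacts (batch effects, probe cross-hybridization, intensity-dependent
variance), to incomplete or noisy trait→MeSH curation, or to the strong
gene–gene correlation of real expression and real disease loci. The planted
effect is also homogeneous across genes, which real compounds are not.

## Numerical choices

- Network averages (genes per compound/disease) round half away from zero,
  the convention that matches reported per-entity means of this kind.
- The fold-change boundary is inclusive on both sides (FC = t counts as up).
- Probes mapped to more than one gene are dropped, not duplicated, to avoid
  double counting; probes with no mapping are dropped.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); results are validated against hand-computed step-up values.
- The pair table sorts by (degenerate-last, q, p, Z descending, compound,
  disease) with a stable mergesort, so ties break deterministically.
- In the exactness tests the boundary is probed with log2 cuts that are
  exactly representable (threshold 2 → cut 1.0) rather than log2(1.5).

## Known limitations

- The observed tested-pair count in a real deployment depends on an upstream
  pre-filter choice (`min_overlap`); no particular pre-filter is assumed by
  default (all pairs are tested).
- The q < 0.2 threshold admits the expected share of background pairs among
  the significant calls (an FDR, not an FWER, guarantee); the synthetic runs
  show 5–15 total calls for 5 planted pairs at 600 tested.
- PPI expansion uses one-hop neighbors of catalog genes only; no transitive
  closure, no intermediate-node inclusion.
- Gene identity is a bare uppercased symbol; no alias resolution.
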