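# Methods

## Model and procedure

The package treats a bulk tumour expression profile as an unknown
composite of malignant and infiltrating cell signals and asks, for each
reference cell lineage, how strongly that lineage's transcriptional
programme is expressed in each sample *relative to the other samples in
the cohort*. The output is a samples × lineages matrix of cell lineage
scores (CLS). The CLS is a rank statistic, not a deconvolution: it does
not estimate cell fractions, and scores are only comparable within a
cohort scored against the same reference.

### Reference weights

Reference panels are log-scale intensity matrices (genes × replicate
arrays) with a replicate→lineage map. The pipeline is deterministic:

1. **Median normalization** — subtract each gene's median across
   columns. "Median normalization" is implemented as subtraction on the
   log scale, which makes the values relative expression levels; a
   ratio interpretation would be equivalent up to exponentiation and
   would not change the subsequent ranks.
2. **z-transform** per column, using the population standard deviation
   (divide by n). The choice of population vs sample sd only rescales
   each column by a constant √(n/(n−1)) and cannot change weight
   *ratios* after the global rescale, but the constant is pinned by
   tests so results are bit-reproducible.
3. **Replicate collapse** — mean z-score per lineage, then re-z each
   collapsed column. Collapsing after (not before) the z-transform
   keeps arrays with different dynamic ranges from dominating the mean.
4. **Split** into an upregulated profile (z > 0, else 0) and a
   downregulated profile (z < 0, else 0).
5. **Weight transform** — non-zero up entries map through the
   upper-tail standard-normal probability, non-zero down entries
   through the lower tail; weights are min(−log₁₀ p, trim) with
   trim = 10 (so p < 10⁻¹⁰ saturates), and both matrices are divided by
   the single global maximum over the pair, giving weights in [0, 1].
   One-sided tails keep the weight monotone in |z| within each profile;
   a two-sided p would carry the same information after the sign split.

Two deliberately open points are implemented behind flags:

- **Split-zeroed entries.** Entries zeroed by the split keep weight
  exactly 0 by default, so a discordant gene contributes no foreground
  mass. A literal tail-probability reading would assign them
  −log₁₀(0.5) ≈ 0.301 pre-rescale — giving every discordant gene a
  uniform nonzero mass; this variant is available via
  `z_to_weights(..., literal_split_weights=True)` (it relaxes the
  up/down mutual-exclusivity invariant).
- **Rescale scope.** The denominator is the single global maximum over
  both matrices jointly, not per profile; per-profile rescaling would
  erase between-lineage differences in differential-expression
  strength.

The **minimal gene set** is the restriction of the up-weight matrix to
genes whose rescaled weight reaches exactly 1 in at least one lineage;
it is a compact signature representation, reported with per-lineage
counts. The **shuffled reference** control permutes each gene's values
independently across columns (value multiset preserved per gene),
destroying lineage coherence while keeping every marginal distribution.

### Scoring

A sample's relative expression is its log expression minus the per-gene
median across samples; genes are ranked high to low, ties broken by
gene symbol (stable and deterministic). For a weight vector w aligned
to the ranking, the foreground curve accumulates w·|g| mass and the
background curve (1−w)·|g| mass, each normalized to end at 1; the
pre-score pCLS is the signed extreme of their difference. The |g| mass
term follows the original formulation of the underlying rank-scoring
algorithm (weighting sorted expression magnitudes); a uniform rank-mass
variant (every gene contributes mass 1) is available via
`mass="rank"`. Genes with zero weight in both profiles still carry
their full (1−w) = 1 background mass; they are never dropped.

Raw pCLS values depend on weight sparsity, so each is normalized by the
mean |pCLS| over permutations of the sample's gene labels
(equivalently: permutations of the weight alignment against the fixed
ranked masses). The final score is CLS = CLS_up − CLS_dn. By default
one permutation stream is drawn per sample and reused across all
lineages and both directions — valid because the null permutes the
sample vector, which is lineage-independent — cutting runtime by
roughly 2× the lineage count; fully independent per-cell permutation is
available (`shared_permutations=False`) for fidelity checks.

Gene spaces are harmonized by case-insensitive symbol identity (murine
"Cd8a" ↔ human "CD8A"), with no ortholog lookup; scoring uses the
intersection, and an error is raised if fewer than 50% of reference
genes match. Zero-filling unmatched genes was considered and rejected:
it would inject artificial concordant mass at the bottom of every
ranking.

### Downstream associations

- **Survival** — one Cox proportional-hazards fit per lineage with the
  CLS as a continuous covariate (lifelines; Efron tie handling), Wald
  p-values, Benjamini–Hochberg adjustment with the family defined as
  all converged lineages in the scan. Non-convergent, constant-score or
  event-free fits are flagged and excluded from the family.
- **Dichotomization** — "about the modal frequency" is operationalized
  as the argmax of a Gaussian kernel density estimate (Silverman
  bandwidth, 2048-point grid over the data range); high = score above
  the mode. A median-split fallback is available when the mode split
  degenerates. Requires ≥ 20 samples.
- **Group comparison** — LI-high vs LI-low groups (median split of the
  infiltration score) are compared with a two-sided Welch t-test; the
  unequal-variance form was chosen because infiltrate-rich groups are
  typically more dispersed.
- **Rank enrichment** — lineages are ranked by Pearson correlation with
  a per-sample annotation; a subtype's enrichment at the top or bottom
  is a one-sided Wilcoxon rank-sum test of member vs non-member
  correlation coefficients, exact enumeration when both groups have
  ≤ 20 members, normal approximation with continuity correction
  otherwise. Both sides are tested and the smaller reported with its
  side label.
- **Profile matching** — Pearson correlation of a query z-profile
  against each panel column over the shared gene space (≥ 100 shared
  genes required), ranked descending.

Missing clinical/annotation fields are dropped pairwise per analysis
with logged counts.

## Synthetic cohorts

`generate_reference` draws per-gene baseline log2 intensities from
N(6, 1) (microarray-like), assigns each lineage a disjoint set of
marker genes shifted up by `effect` log2 units (default 3.0 — a
strong, cleanly separable cell-type programme), and adds N(0,
`noise_sd`) replicate noise (default 0.3). `generate_tumours` mixes
the lineage archetypes on the *intensity* scale with Dirichlet(0.5·1)
fractions (sparse infiltrates: most samples dominated by a few
lineages), logs the composite, and adds N(0, 0.3) tumour-intrinsic
gene noise. `generate_survival` draws exponential event times with
hazard `baseline · exp(Σ βk · z(fraction_k))` (fractions standardized,
so β is a per-sd log hazard ratio) and independent exponential
censoring. Defaults: 3 replicates per lineage and 50 markers per
lineage on the `recovery-small` preset (10 lineages, 5,000 genes, 200
samples, 200 permutations) — sizes chosen so the full pipeline runs in
minutes on one CPU while leaving ample signal and sample size for the
recovery and survival checks.

What the generator does *not* emulate: platform-specific noise
(probe effects, saturation), batch structure, correlated gene modules
within a programme, copy-number-driven expression, a malignant-cell
archetype distinct from the lineage mixture, and informative
censoring. Passing recovery tests therefore demonstrate the method's
internal correctness and its behaviour under its own modelling
assumptions, not performance on real cohorts.

### A known limitation of the shuffled control at small lineage counts

With only 10 lineages × 3 replicates, shuffling each gene's values
across the 30 columns leaves a non-trivial chance that a true marker
gene's high values land in the column block of some shuffled lineage.
Shuffled profiles therefore absorb genuine markers of random lineages
and retain real — not chance — correlation with the corresponding
mixing fractions (observed per-lineage |Spearman| up to ≈ 0.3 on the
preset). This binomial assignment noise does not shrink with more
marker genes; it shrinks with more lineages, and is negligible for
panels with hundreds of cell types. The shuffled-control test asserts
the idealized band (|Spearman| < 0.2 for every lineage) and is expected
to fail at this panel size; the acceptance script reports the measured
maximum honestly.

## Numerical choices

- pCLS excursions below 10⁻¹⁴ are snapped to exactly 0: the curves are
  two unit-scale CDFs, so anything smaller is accumulated rounding
  residue (a mathematically zero deviation, e.g. constant weights,
  reports exactly 0).
- Ties: equal |pCLS⁺| and |pCLS⁻| return the positive excursion; equal
  probe means collapse to the lexicographically smallest probe id;
  equal expression ranks order by gene symbol. All measure-zero for
  real data, pinned for determinism.
- Permutations are index matrices from `numpy.random.default_rng`
  (PCG64), drawn as argsorts of uniforms; results are reproducible
  given (seed, numpy generator algorithm).
- The streaming curve computation is validated against a brute-force
  O(n²) double-summation oracle to 10⁻¹² on random instances.
- Readers reject missing and non-numeric cells rather than imputing;
  single-column median normalization and zero-variance z-transforms
  are errors, not warnings.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `trim` | 10 | cap on −log₁₀ p weights; saturates p < 10⁻¹⁰ |
| `n_perm` | 1000 | permutations per sample for score normalization |
| `mass` | `"abs"` | per-gene cumulative mass: \|g\| or uniform rank mass |
| `shared_permutations` | True | one null stream per sample vs per cell |
| `match_floor` | 0.5 | minimum matched fraction of reference genes |
| `effect` | 3.0 log2 | marker up-shift in simulated references |
| `noise_sd` / `tumour_intrinsic_sd` | 0.3 | replicate / tumour gene noise (log2) |
| `dirichlet_alpha` | 0.5 | mixing sparsity of simulated cohorts |
| `censor_rate` | 0.02 | exponential censoring rate in simulated survival |

## Known limitations

Scores are cohort-relative; adding or removing samples changes the
median normalization and hence every score. The permutation null
treats genes as exchangeable and independent, which real co-expression
violates; normalized scores are calibrated in location (mean ≈ 0 under
the null) but their scale should not be read as a z-score. The
mode-based dichotomization is sensitive to bandwidth in small cohorts
(< 50 samples); prefer the median fallback there.
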