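# Methods

This document records the statistical and algorithmic choices behind each
pipeline stage, the parameters with their defaults and rationale, what the
synthetic generator does and does not emulate, and known limitations.

## 1. Metabolomics preparation (`gutlink.metabolomics`)

Peak-area tables arrive as one matrix per acquisition method (metabolites ×
samples, non-negative). Processing per method:

1. **Participant filter.** Keep participants with ≥ `min_samples` (default 3)
   samples covering ≥ 2 distinct timepoints, so within-participant structure
   is estimable.
2. **Total-sum scaling (TSS).** Each sample is divided by its column sum,
   turning peak areas into relative abundances. A sample whose areas are all
   zero is an error (named in the message), not silently dropped.
3. **Pseudocount.** Half the smallest nonzero relative abundance *within
   that method* is added before taking logs. Tying the pseudocount to the
   method's own detection floor keeps the imputed value below anything
   actually observed without a global magic number.
4. **Log-ratio transform.** Relative abundances are compositional; raw logs
   of proportions induce spurious negative correlation. The default is the
   centered log-ratio (CLR). The isometric log-ratio (ILR) is also
   available, built from the normalized Helmert basis
   (`scipy.linalg.helmert`); ILR coordinates are back-projected through the
   basis transpose, which reproduces the CLR representation exactly, so
   downstream stages always see one metabolite-indexed matrix regardless of
   the transform choice.
5. **Cross-method averaging.** Transformed values for the same metabolite
   measured by several methods are averaged over the samples the methods
   share. Methods are simulated with partial coverage
   (`method_coverage = 0.8`), so averaging also fills in single-method
   metabolites.
6. **Outlier removal.** PCA (two components) on the averaged matrix; samples
   farther than `k_sd` (default 3) standard deviations from the mean on PC1
   or PC2 are removed, and the provenance records which.

## 2. Differential abundance (`gutlink.abundance`)

Per metabolite and per contrast (CD vs non-IBD, UC vs non-IBD):

- **Effect size.** Difference of group means of the transformed abundances,
  with a BCa bootstrap confidence interval
  (`scipy.stats.bootstrap(method="BCa")`, `n_boot = 5000`). Zero-variance
  inputs short-circuit to a degenerate interval; a NaN interval (possible
  when the jackknife acceleration is undefined) falls back to the point
  estimate, and the interval is clamped to contain it.
- **Test.** Mann-Whitney U. When both groups have ≤ 8 observations the
  p-value is computed by exact enumeration over all label assignments
  (tie-safe: a permutation counts when its deviation is ≥ observed − 1e−9);
  otherwise the scipy asymptotic tie-corrected normal approximation is used.
  The exact path matters because small per-timepoint strata are common.
- **Multiplicity.** Benjamini–Hochberg within each contrast
  (`statsmodels.stats.multitest.multipletests`); `significant` means
  q ≤ `fdr` (default 0.05).
- **Fold change.** `log10` of the ratio of mean relative abundances
  (pseudocounted), computed on the TSS scale rather than the transformed
  scale so it reads as an abundance ratio.

Each call draws its resampling generator from a spawned child of the
pipeline seed, so adding or removing metabolites does not perturb the
streams of the others.

## 3. Differential expression (`gutlink.expression`)

A negative-binomial Wald pipeline in the style of median-of-ratios
count models, implemented on statsmodels:

- **Size factors.** Median of ratios to the per-gene geometric mean
  (all-zero genes excluded), rescaled to geometric mean 1.
- **Design.** `~ diagnosis * is_ileum` with non-IBD as reference:
  intercept, CD, UC, is_ileum, CD:is_ileum, UC:is_ileum. `is_ileum` is
  derived from biopsy location with a strict whitelist; an unknown label is
  an error rather than a silent false.
- **Dispersion.** Per-gene method-of-moments estimates within design cells
  (bias-corrected by n/(n−p)), then shrunk 50% in log space toward a fitted
  `a1 + a0/μ` trend, clipped to [1e−8, 10]. This is a deliberately simple
  stand-in for full empirical-Bayes dispersion shrinkage: on the data sizes
  used here its log2-fold-change estimates correlate > 0.95 with an
  external DESeq2 implementation (checked in the test suite when that
  package is importable), which is sufficient for calling planted effects.
- **Tests.** Per-gene NB GLM (`sm.GLM` with `NegativeBinomial(alpha)`
  family, `offset = log(size factor)`), Wald tests on the CD and UC main
  effects, BH within each contrast. Rank-deficient designs are rejected up
  front with the confounded columns named.

The in-package implementation (rather than wrapping an external DE package)
keeps the stage pure-Python, single-threaded, dependency-light and exactly
reproducible; the trade-off is the cruder dispersion shrinkage noted above.

## 4. Consensus ranking (`gutlink.ranking`)

Features are the transformed metabolite abundances plus site code,
antibiotics flag and age (never used as importance outputs). The split is
**participant-disjoint** and stratified by diagnosis (default holdout 15%):
repeated samples from one participant must not straddle train/test or
accuracies are inflated.

- **Model zoo.** Eight classifiers (logistic regression, k-NN, random
  forest, a small dense network, Gaussian naive Bayes, linear one-vs-rest
  SVM, XGBoost, mixed-effects XGBoost) are scored by weighted F1 on the
  holdout; scale-sensitive models run inside standardization pipelines. The
  zoo is descriptive context for the report — consensus components always
  come from the two boosted models, regardless of which zoo model wins.
  Holdout scoring (rather than nested CV) was chosen to keep the zoo cheap;
  the zoo's numbers are not used for selection, so its variance is
  acceptable.
- **Tuned GBM.** Grid search (5-fold stratified CV on the training
  participants, weighted F1, default grid: max_depth {2,4,6}, learning rate
  {0.05,0.1,0.3}, estimators {100,300}), refit on all training data.
  Components: gain (s2), split count / "weight" (s3), and per-state mean
  |SHAP| (s4). SHAP values come from XGBoost's native TreeSHAP
  (`pred_contribs=True`), which is exact for tree ensembles and avoids an
  extra dependency.
- **Mixed-effects GBM.** Repeated sampling of participants and shared
  collection sites violate the i.i.d. assumption of plain boosting, so a
  GMERF-style model alternates, per one-vs-rest class:
  1. Fit XGBoost with the current random intercepts (participant + site) as
     `base_margin`.
  2. Form working residuals on the logit scale,
     `r = offset + (y − p)/w` with `w = p(1−p)`, clipped to ±10.
  3. Re-estimate the intercept variance by a **method-of-moments** step:
     `σ² = max(0, var(weighted cluster means) − mean(1/Σw))`, then shrink
     cluster means by the BLUP factor `σ²/(σ² + 1/Σw)`. Intercepts are
     re-centered each iteration.
  The moment estimator was chosen over an EM-style
  `σ² = mean(b² + conditional var)` update because the latter approaches
  zero only harmonically when there is no cluster effect, leaving inflated
  σ estimates after any practical number of iterations; the moment form is
  unbiased to first order and hits zero immediately on null data (verified
  in the tests: planted SD 1.0 recovered within [0.5, 2.0]; null data gives
  σ ≤ 0.1). Unseen clusters at prediction time get intercept 0. Components:
  gain (s5) and split count (s6), averaged over the class models.
- **Significance component.** s1 = min-max scaled `−log10 q` from the
  Mann-Whitney stage, with q floored at 1e−10 so one extreme q-value cannot
  flatten every other metabolite.
- **Aggregation.** Per (metabolite, state): raw mean of s1…s6, min-max
  scaled over *all* rows, then square-root transformed (the square root
  spreads the lower range, where most metabolites sit). Candidates are the
  top quartile per state (≥ the 75th percentile, ties included), and the
  final candidate set is the union over states.

## 5. Chemical screening (`gutlink.chem`)

- **Fingerprints.** RDKit 2048-bit path fingerprints (default; Morgan
  available). A fingerprint is stored as a frozen bit set tagged with its
  generation parameters; similarity between fingerprints of different
  parameters is an error.
- **Similarity.** Tanimoto `c/(c+a+b)` and Tversky `c/(c+αa+βb)` with
  `α = 0.05`, `β = 1 − α`, metabolite as first operand. The asymmetric
  Tversky arm deliberately rewards metabolites whose features are a
  near-subset of a larger library compound (substructure-like matches) that
  Tanimoto would miss.
- **Thresholds.** A hit qualifies by Tanimoto ≥ 0.85 **or** Tversky ≥ 0.95;
  the qualifying arm is recorded. Hits are joined to assay records
  restricted to functional assay classes (keyword classifier over assay
  descriptions), kept at pxC50 ≥ 5.5 (~3 µM), and aggregated per
  (compound, target) with best pxC50 and range retained.
- **Pleiotropy.** Metabolites or targets touching ≥ `max_degree` (default
  20) partners are removed in a single simultaneous pass (both degree
  tables computed before any removal), since promiscuous nodes contribute
  noise rather than mechanism. Degree histograms are kept as diagnostics.
- **Classification.** Pair similarity is labeled medium (0.8–0.9) or strong
  (> 0.9); affinity medium (5.5–7.0) or strong (> 7.0). Pharmacological
  direction comes from an ordered keyword map over the assay action string
  ("inverse agonist" and "negative allosteric" match before bare
  "agonist", etc.).

## 6. Evidence integration (`gutlink.integrate`)

Each screened pair is expanded to one row per disease state and annotated
with the metabolite's DA result and the target gene's DE result. The
co-directionality class requires both q ≤ 0.05 and a known pharmacological
direction:

| target gene | direction | metabolite | class |
|---|---|---|---|
| up | negative | down | `compensatory_up` |
| down | positive | down | `codirectional_down` |
| up | positive | up | `concordant_up` |
| down | negative | up | `concordant_down` |
| anything else | | | `unknown` |

Genetic evidence (trait annotations per gene) is filtered by
case-insensitive keyword match (defaults: inflammatory, Crohn, colitis,
monocyte, lymphocyte); curated sources (OMIM, reviewed entries) pass
unconditionally. Summaries count unique pairs, directed pairs, pairs with
genetic evidence and the class distribution, optionally restricted to
consensus candidates or to DEG targets.

## 7. Synthetic generator (`gutlink.synthetic`)

All randomness derives from one `numpy.random.SeedSequence`, spawned into
independent child streams (metabolomics, transcriptomics, chemistry,
genetics, misc), so each modality is reproducible in isolation.

**What it emulates**

- *Metabolomics:* `log10(area) = baseline N(6,1) + disease effect +
  participant intercept N(0, 0.2²) + site intercept N(0, 0.1²) + method
  offset N(0, 0.2²) + noise N(0, 0.3²)`, exponentiated to peak areas; 4
  methods at 80% coverage; 20 planted differentially abundant metabolites
  with |log10 FC| in [0.3, 1.0].
- *Transcriptomics:* NB counts, dispersion 0.1, library sizes geometrically
  spaced in [0.5, 2.0]× and shuffled; 100 planted DEGs at |log2 FC| = 2; a
  10% gene subset carries an ileum effect (SD 1.0).
- *Chemistry:* 300 library compounds = planted analogs + 20 decoy
  scaffolds (verified below both similarity thresholds against every
  metabolite template). Analogs are generated by small string edits of real
  metabolite SMILES (chain homologation, O→N swap, N-methylation, ring
  methyl, terminal carbon) and **validated** to pass the thresholds against
  their parent only and fail against every other template; parents with no
  non-clashing edit are excluded, and the generator errors if fewer viable
  parents exist than analogs requested. Planted analogs carry one
  functional, directed assay with pxC50 ~ U(4.8, 9.0).
- *Coordination:* analog parents are a subset of the planted DA
  metabolites; each planted target's gene is a planted DEG whose sign obeys
  `sign(target DE) = sign(metabolite DA) × sign(direction)`, so every
  planted chain lands in a named co-directionality class; evidence-bearing
  targets are a subset of the assigned targets. Ground truth for every
  planted element is written alongside the data.

**What it does not emulate:** longitudinal trajectories (timepoints shift
nothing), metabolite–metabolite correlation beyond the compositional
closure, missingness mechanisms other than method coverage, batch drift
within a method, isomeric ambiguity of identifications, or realistic
assay-measurement error models.

**Default problem sizes** (90 participants, split 0.40/0.27/0.33 across
non-IBD/CD/UC; 200 metabolites; 2000 genes; 300 compounds; 60 targets) were
chosen so the full pipeline completes in a few minutes on one CPU while
leaving every stage's statistics non-trivial (exact-test strata, BH at
realistic densities, grid search over a non-degenerate surface).

## 8. Pipeline and formats (`gutlink.pipeline`, `gutlink.cli`)

Configuration is a pydantic model (`extra="forbid"`, so typos fail fast)
loadable from YAML; every numeric field is range-validated. Stages run in
fixed order; a stage subset reuses cached upstream artifacts and errors if
they are missing required columns (named in the message). All floating
output uses `%.6g`; `manifest.json` records package version, configuration,
per-stage parameters/counts and a sha256 per artifact, so identical
(config, seed) runs are byte-identical. CLI exit codes: 0 success,
2 configuration error, 3 stage failure.

## Limitations

- The DE stage's dispersion shrinkage is a moment/trend approximation, not
  full empirical Bayes; borderline genes near the FDR boundary may differ
  from heavier implementations.
- The mixed-effects GBM estimates a single intercept variance per grouping
  factor per class and assumes logit-scale additivity of the random
  effects.
- BCa intervals degrade for very small groups (the jackknife acceleration
  can be undefined; the fallback interval is then the point estimate).
- Similarity screening is exhaustive (O(queries × library)); fine for
  thousands of compounds, not for full-scale bioactivity databases without
  prefiltering.
- Keyword-based assay and trait classification is intentionally simple and
  will misclassify descriptions outside its vocabulary.
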