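# Methods

`lncsig` implements a two-class molecular-subtype signature workflow for bulk
expression cohorts, with diffuse large B-cell lymphoma (ABC vs. GCB
cell-of-origin subtypes) as the motivating system. This note documents the
statistical procedure, the simulator that stands in for patient cohorts, the
numerical conventions, and the limits of what the synthetic results show.

## The classification model

For each signature gene *L*, training samples of the two classes yield means
and sample standard deviations (μ_ABC, μ_GCB, σ_ABC, σ_GCB). The gene's
weight is its signal-to-noise ratio and its decision boundary the midpoint of
the class means:

    w_L = (μ_ABC − μ_GCB) / (σ_ABC + σ_GCB),     b_L = (μ_ABC + μ_GCB) / 2.

A test sample with expression e_L casts, per gene, a vote of magnitude
|w_L| · |e_L − b_L|. The side of the boundary the sample falls on, combined
with the sign of the weight, decides which class receives the vote:
sign(w_L)·(e_L − b_L) > 0 supports ABC, < 0 supports GCB, and a sample exactly
on a boundary contributes nothing for that gene. The class with the larger
vote total V wins; the margin (V_ABC − V_GCB)/(V_ABC + V_GCB) ∈ [−1, 1] is
the continuous score used for ROC analysis, and V_ABC/(V_ABC + V_GCB) is
reported as `prob_abc`. Exact vote ties (a measure-zero event) go to the
majority training class, with a warning.

Two denominator conventions for w_L are implemented. `mode="sum"` (the
default) is the classical signal-to-noise weight and is defined whenever
either class has positive variance. `mode="difference"` divides by
(σ_ABC − σ_GCB) instead; it is retained for comparison runs but is undefined
for any gene whose class standard deviations coincide, and its sign depends
on which class is noisier, so it is not recommended. Genes with an undefined
weight are dropped at training time; training on an empty usable set is an
error rather than a silent fallback.

Because weights are ratios of location to scale, a global affine transform
e → a·e + c (a > 0) of the expression data leaves every predicted label
unchanged (votes scale by a); this invariance is property-tested.

A fitted model can be **restricted** to the subset of its genes measured on
another platform; the stored per-gene parameters are reused verbatim, with no
re-estimation. This mirrors applying a signature to an array that covers only
some of its genes.

## Candidate screening

Genes are screened with an unpaired two-tailed pooled-variance t-test between
the classes; p-values are adjusted by Benjamini–Hochberg step-up over all
*tested* genes, and a gene passes at p < 0.01 and FDR < 0.15 (both
configurable). Genes with zero pooled variance cannot be tested; they are
reported with missing statistics and excluded from the BH family, since an
untested hypothesis carries no p-value. FDR is computed over the full tested
set rather than a pre-filtered one — the standard BH practice.

## Signature-size selection

The candidate pool is fixed once (screen on the full discovery cohort); the
per-gene *ranking*, however, is recomputed inside every training fold so that
selection is honest about ranking uncertainty. The procedure:

1. For each of P permutations, draw a fresh stratified 5-fold split.
2. Within each training fold, rank candidates by |w_L| computed on training
   samples only (ties broken by gene id for determinism).
3. For each candidate size N, classify the held-out fold with a
   weighted-voting model on the fold's top-N genes.
4. average_error_N = (total misclassified held-out samples across all folds
   and permutations) / P — the mean number of misclassified cohort samples
   per cross-validation round.

The signature size k is the smallest N whose average error is within
`tolerance` (default 1.0 misclassified sample) of the curve minimum. This
formalises "the smallest signature whose accuracy is essentially as good as
the best": growing the signature past k buys back less than one sample per
round. The k signature genes are then the genes most frequently contained in
the top-k of the folds' ranking lists (5·P lists in total), ties broken by
better mean rank, then lexicographically. The final model is trained on the
full discovery cohort restricted to those k genes.

Because the candidate pool comes from a screen on the full cohort, the error
curve is not a fully unbiased accuracy estimate (the screen has seen the
held-out samples). This leakage is inherent to the screen-then-select design;
the curve is used only to pick k, and honest performance claims should come
from independent cohorts, as in `run_validation`.

Note a structural interaction between the size rule and recovery metrics:
when the planted (or true) markers separate the classes easily, the error
curve reaches its floor well before the full marker count, and the
within-tolerance rule deliberately picks a *smaller* signature. Recall of the
complete marker set is then bounded by k / (number of markers) even though
essentially every selected gene is a true marker (precision ≈ 1). On harder
problems the curve floor moves right and k grows toward the marker count.

## Evaluation

ABC is the positive class everywhere: sensitivity is the fraction of ABC
samples predicted ABC, specificity the GCB analogue; percentages are reported
to one decimal. AUC is the Mann–Whitney concordance probability of the vote
margin (mid-rank ties count one half) — any monotone transform of the score,
including `prob_abc`, gives the identical AUC. Unsupervised structure is
assessed by complete-linkage agglomerative clustering of samples under
euclidean distance, cut at two clusters, and a Pearson chi-square (df=1, no
continuity correction — expected counts are large in the intended uses)
between cluster membership and subtype.

## Survival analysis

Kaplan–Meier estimation, the log-rank test and Cox proportional-hazards fits
are delegated to `lifelines`; the module fixes the conventions:

- Rates at a horizon (e.g. 5-year = 60 months) are read from the
  right-continuous KM step function: the value after the last event at or
  before the horizon.
- Medians are reported as not-reached when S never drops to 0.5 or below.
- Cox fits use Efron tie handling with Wald confidence intervals and p-values
  (lifelines implements Efron only; a Breslow option is deliberately not
  faked — requesting it raises). Under Efron, duplicating every subject
  shifts the estimate slightly because duplication creates ties; the exact
  duplication invariance familiar from the untied partial likelihood holds
  only approximately (tested at |Δβ| ≤ 0.05).
- Missing covariates are handled complete-case per fit, with the dropped
  count logged; imputation is never performed.
- Stratified analyses repeat the predicted-ABC-like vs GCB-like contrast
  (KM + log-rank + univariate Cox) within each level of a clinical factor; a
  stratum containing only one predicted group is reported as not testable.

## Co-expression

For each signature lncRNA, Pearson correlations with every mRNA profile are
computed across the shared samples, mRNAs are ranked by r descending
(ties by gene id) and the top ceil(fraction · n_mrna) kept per lncRNA
(fraction default 0.5%). The deduplicated union keeps only positively
correlated mRNAs, matching the convention that functional context is imputed
from positive co-expression. Constant mRNA rows have undefined correlation
and are excluded with a warning.

## The synthetic cohort generator

The simulator emulates a normalised two-subtype cohort, not raw arrays:

- **Expression** is Gaussian in z-score space. Planted markers get a mean
  shift of `effect_size` (z-units, before the final per-row rescaling) in one
  subtype; `direction_abc_fraction` (default ≈ 0.36) controls the share
  shifted upward in ABC. Non-markers are exchangeable between subtypes. Rows
  are z-scored (sample sd) at the end, which preserves t-statistics, SNR
  ranks and correlations.
- **Which genes are informative is a population property**: marker
  identities, directions and co-expression partners derive from a seed
  computed from the structural config fields, so two cohorts differing only
  in the sampling seed share ground truth — exactly what discovery/validation
  pairs need.
- **mRNA co-expression**: each marker gets `n_coexpressed_per_marker`
  partner mRNAs built as r·z(lncRNA) + √(1−r²)·noise (default r = 0.8).
- **Survival** is exponential; the GCB scale is set by `surv_median_gcb`
  (default 112 months, i.e. ~69% five-year survival) and the ABC hazard is
  multiplied by `hazard_ratio_abc` (default 1.6, in the range reported for
  cell-of-origin contrasts). Censoring is an independent exponential whose
  rate makes a GCB patient censored with probability `censor_rate` (default
  0.6, matching the alive fraction typical of such cohorts). Progression-free
  survival uses the same structure with a 1.3× hazard.
- **Clinical covariates** (age ≥60, gender, stage III/IV, high LDH, ≥2
  extranodal sites, ECOG ≥2) are independent Bernoulli draws at
  cohort-typical frequencies, prognostically inert by default, with optional
  missingness (`missing_clinical_rate`).
- The ground truth is written to a separate `truth.json`, never into the
  clinical table, so estimators cannot consume it by accident.

Defaults mirror the motivating study's scale: 426 patients at a 199/227
ABC/GCB split, 2330 lncRNA features with 156 informative, and a 20 000-gene
mRNA compendium.

What the simulator deliberately does **not** model: probe-level intensities,
batch effects, correlated (block) noise between genes, platform differences,
informative censoring, or prognostic clinical covariates (the last two are
available as config extensions but default off). Tests passing on this
generator therefore demonstrate correctness of the *procedure* under the
stated generative assumptions — not classifier performance on real arrays,
where correlated noise typically inflates cross-validated error and pushes
the selected signature size upward.

## Numerical conventions and scaled-down defaults

- Z-scores and class standard deviations use the sample convention (ddof=1);
  population sd is available via an argument.
- Constant expression rows z-score to all zeros (zero weight, zero vote
  downstream) with a warning rather than erroring.
- All randomness flows through `numpy.random.default_rng`/`SeedSequence`
  children of a single seed; CV fold draws use per-permutation seeds, so
  every pipeline run is reproducible bit-for-bit and written outputs are
  byte-identical across repeated runs.
- TSV outputs are UTF-8, tab-delimited, floats at 6 significant digits, with
  a header comment carrying the config hash and seed.
- Test and acceptance simulations run at reduced problem sizes chosen as this
  package's own study conditions (e.g. 200-sample cohorts with 500 genes and
  20 CV permutations instead of 100; 300–500 replicate calibration loops);
  the statistical checks are calibrated to have stable pass probabilities at
  those sizes.

## Known limitations

- The difference-denominator weight mode is implemented for fidelity but
  drops genes freely; results in that mode are not comparable across cohorts
  with different variance structure.
- The error-curve selection is not nested cross-validation; its accuracy
  values are optimistic (see leakage note above).
- Cox fitting offers Efron ties only.
- The abstention band ("unclassified" samples near prob_abc = 0.5) is not
  applied by default; every sample receives a label.
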