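# lncsig

Weighted-voting lncRNA subtype signatures for two-class expression cohorts:
discovery, cross-validated signature-size selection, independent-cohort
validation, and survival association.

## The problem

Diffuse large B-cell lymphoma (DLBCL) splits into two cell-of-origin
subtypes — activated B-cell-like (ABC) and germinal-center B-cell-like
(GCB) — with distinct prognosis. Long non-coding RNAs are strongly tissue-
and subtype-specific, so a small panel of lncRNAs can carry the subtype
label. `lncsig` provides the full workflow for building and validating such a
panel from gene-by-sample expression matrices (z-scored intensities) plus a
clinical table, and a synthetic-cohort generator so every stage is testable
without patient data.

## The method

**Screen.** Each lncRNA is tested between subtypes with a pooled-variance
t-test; Benjamini–Hochberg FDR over all tested genes; candidates pass at
p < 0.01 and FDR < 0.15.

**Classify.** For signature gene *L* with class statistics (μ_ABC, μ_GCB,
σ_ABC, σ_GCB):

    w_L = (μ_ABC − μ_GCB)/(σ_ABC + σ_GCB),    b_L = (μ_ABC + μ_GCB)/2.

A sample with expression e_L casts a vote |w_L|·|e_L − b_L| for ABC when
sign(w_L)·(e_L − b_L) > 0, else for GCB; the larger total V wins, and
(V_ABC − V_GCB)/(V_ABC + V_GCB) is the continuous score for ROC analysis.

**Select the size.** Stratified 5-fold cross-validation with repeated
permutations; within each training fold candidates are re-ranked by |w_L| and
the top-N model classifies the held-out fold. The signature size k is the
smallest N whose average misclassification count is within one sample of the
curve minimum, and the k genes are the most frequent top-k members across all
fold-level rankings. The final model is fitted on the whole discovery cohort.

**Validate and survive.** A frozen model applies to further cohorts,
auto-restricting to the genes a platform measures (no refitting). Predicted
ABC-like vs GCB-like groups are contrasted with Kaplan–Meier curves, the
log-rank test and Cox proportional-hazards fits (uni-/multivariate,
stratified by clinical factors). Signature lncRNAs are linked to mRNAs by
Pearson co-expression (top 0.5% per lncRNA) for downstream functional
inference.

See `docs/methods.md` for conventions, the simulator's generative model, and
known limitations.

## Worked example

```python
import dataclasses
from lncsig import (SimConfig, PipelineConfig, generate_cohort,
                    run_discovery, run_validation)

sim = SimConfig(n_samples=200, n_lnc=500, n_informative=15, effect_size=1.5,
                n_mrna=2000, n_coexpressed_per_marker=5, censor_rate=0.2,
                missing_clinical_rate=0.0, seed=1)
cohort = generate_cohort(sim)                       # 200 patients, 15 planted markers
cfg = PipelineConfig(permutations=20, seed=1)
disc = run_discovery(cohort.lnc_matrix, cohort.annotation, cfg)

fresh = generate_cohort(dataclasses.replace(sim, seed=2))
val = run_validation(disc.model,
                     {"fresh": (fresh.lnc_matrix, fresh.annotation)}, cfg)["fresh"]
```

Output of this exact run:

```
candidates passing screen : 18
chosen signature size k   : 11
selected ∩ planted        : 11/11
training accuracy         : 100.0%
training AUC              : 1.000
OS log-rank p             : 0.0026
OS hazard ratio (ABC-like): 1.622 (1.181-2.227)
validation accuracy       : 99.5%  AUC 1.000
```

Reading it: the differential screen keeps 18 of 500 lncRNAs (the 15 planted
markers plus 3 false positives); the cross-validated error curve settles on
an 11-gene signature, all 11 of which are planted markers; the frozen model
classifies an independent cohort drawn from the same population at 99.5%
accuracy; and the predicted ABC-like group shows the planted survival
disadvantage (true hazard ratio 1.6, estimated 1.62 with a CI excluding 1).

The same workflow is scriptable from a shell:

```sh
lncsig simulate --config sim.yaml --out cohort --seed 5
lncsig split --expr cohort/lnc_expr.tsv --clinical cohort/clinical.tsv --out halves
lncsig run-discovery --expr halves/discovery/expr.tsv \
       --clinical halves/discovery/clinical.tsv --out disc --seed 2
lncsig run-validation --model disc/model.json \
       --cohort val halves/validation/expr.tsv halves/validation/clinical.tsv \
       --out valout
```

`run-discovery` writes every stage as a TSV/JSON (`diffexp.tsv`,
`cv_curve.tsv`, `signature.json`, `model.json`, `predictions.tsv`,
`metrics.tsv`, `survival.tsv`, `cox.tsv`), each stamped with the config hash
and seed; repeated runs with the same seed are byte-identical.

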