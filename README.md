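# gradalign

**Orthogonal Procrustes alignment of functional-connectivity gradients —
and what the number of aligned gradients does to everything downstream.**

Functional gradients are low-dimensional spectral embeddings of a
functional-connectivity (FC) matrix: each cortical parcel receives a
coordinate along axes of smooth connectivity variation. Before subject-level
gradients can be compared or pooled they must be aligned to a common
reference, because eigenvector sign is arbitrary and component order can
swap between subjects and scanning sessions. The standard fix is orthogonal
Procrustes alignment — but the aligned *principal* gradient then becomes a
linear mixture of **all** gradients entering the alignment, and the choice
of how many gradients to use quietly changes subject identifiability,
motion sensitivity, and prediction results.

`gradalign` implements the full analysis pipeline for studying this effect:

- **connectivity** — Pearson FC, Fisher-z group averages, framewise
  displacement (FD), typicality of functional connectivity (TFC),
  parcel-wise BOLD–FD correlations, KS comparisons of correlation
  distributions;
- **embedding** — row sparsification, five affinity kernels (gaussian,
  cosine, normalized angle, Pearson, Spearman), and three spectral
  reductions: diffusion maps, PCA, Laplacian eigenmaps
  (`GradientMaps` estimator);
- **procrustes** — the closed-form orthogonal alignment and its
  diagnostics (`ProcrustesAlignment` transformer);
- **identifiability** — connectome fingerprinting: identification accuracy
  and differential identifiability over session pairs;
- **prediction** — 10×5-fold nested cross-validation with CV-consistent
  confound removal (ridge, linear/RBF SVM, random forest);
- **cohort** — a synthetic multi-session cohort generator so every stage is
  testable end to end without any imaging data;
- **pipeline / CLI** — holdout split, reference construction, sweeps over
  the number of aligned gradients, BH-FDR-corrected motion-correlation
  tables.

## The core computation

Let **A** (P parcels × n gradients) be a subject's gradient matrix and
**B** the reference. Orthogonal Procrustes seeks the orthogonal **T**
minimising ‖**AT** − **B**‖_F; with the cross-covariance
**C** = (**B**ᵀ**A**)ᵀ and SVD **C** = **UΣV**ᵀ, the minimiser is
**T** = **UV**ᵀ (no centering, no scaling, no iterative refinement).
Scalar diagnostics of the fitted transform:

- *correspondence* c = max<sub>i</sub>|t<sub>i1</sub>| / Σ<sub>i</sub>|t<sub>i1</sub>| —
  how much a single unaligned gradient dominates the aligned principal
  gradient (1 = pure sign/order fix, →1/n = fully mixed);
- *Trans_Total* = Σ<sub>ij</sub>|t<sub>ij</sub>| and *Trans_PG* =
  Σ<sub>i</sub>|t<sub>i1</sub>| — transformation-magnitude heuristics;
- ‖w‖₂ — ℓ₂-norm of the singular values of **C**, and ‖Θ‖₂ — ℓ₂-norm of the
  principal angles between the column spans: opposing indicators of
  subspace similarity.

Downstream, the aligned principal gradient feeds fingerprinting
(identification accuracy; I<sub>Diff</sub> = (I<sub>self</sub> −
I<sub>other</sub>) × 100, with or without Fisher r-to-z), motion analyses
(FD; TFC = (1 + r(FC, FC̄))/2), and nested-CV prediction.

## Worked example

Simulate a 12-subject, 2-session cohort and run the full study:

```bash
gradalign simulate --output-dir demo_cohort --seed 42 --n-subjects 12
gradalign run-all demo_cohort --config demo_config.yaml \
    --output-dir demo_results --seed 42
```

with `demo_config.yaml`:

```yaml
n_components_extracted: 10
n_align_values: [1, 2, 5, 10]
prediction_n_align: [10]
cv: {outer_folds: 3, outer_repeats: 2, inner_folds: 3}
```

Summarising two of the emitted tables:

```python
import pandas as pd
d = pd.read_csv("demo_results/alignment_diagnostics.csv")
print(d.groupby("n_align")[["correspondence", "trans_total", "theta_norm"]]
        .mean().round(3))
i = pd.read_csv("demo_results/identifiability.csv")
print(i[i.variant == "fisher_z"]
        .groupby("n_align")[["accuracy", "i_diff"]].mean().round(3))
```

prints

```
         correspondence  trans_total  theta_norm
n_align
1                 1.000        1.000       1.337
2                 0.773        2.451       1.826
5                 0.431        9.289       2.696
10                0.249       25.860       3.495

         accuracy  i_diff
n_align
1            0.20  12.809
2            0.50  36.336
5            0.60  34.749
10           0.75  32.761
```

Reading: with one gradient the alignment can only flip a sign
(correspondence 1, Trans_Total 1) and subjects are barely identifiable
across sessions (accuracy 0.20). Using 10 gradients, the aligned principal
gradient mixes heavily (correspondence 0.249) and identification accuracy
rises to 0.75 — the alignment is importing subject-specific information
from the lower gradients. The `motion_correlations.csv` table tracks how
much of that imported information co-varies with head motion.

The same stages are available as library calls (`generate_cohort`,
`extract_gradients`, `align_to_reference`, `sweep_identifiability`,
`nested_cv_regression`, `run_full_study`); see `docs/methods.md` for the
model and its assumptions.

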