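# Methods

This note documents the models, numerical choices, and design decisions
behind `gradalign`, and what the synthetic cohort does and does not
emulate.

## Gradient extraction

FC matrices are pairwise Pearson correlations of parcellated BOLD series
(diagonal fixed at exactly 1). Extraction is a three-stage pipeline:

1. **Row sparsification.** Independently per row, entries strictly below
   the row's `sparsity` quantile are zeroed (default 0.9, i.e. the top 10 %
   of each row's connections survive). The sparsified matrix need not be
   symmetric; symmetry is restored by the kernel stage, which operates on
   pairs of sparsified row vectors.
2. **Affinity kernel.** gaussian `exp(−γ‖x−y‖²)` (γ defaults to 1/P),
   cosine, normalized angle `1 − arccos(cossim)/π`, Pearson (cosine of
   centered rows), Spearman (Pearson of within-row ranks), or `none`
   (pass-through). Negative affinities are clipped to 0 before the graph
   embeddings, which require non-negative weights.
3. **Spectral reduction.**
   - *Diffusion maps* (default): anisotropic normalization with α = 0.5
     (W = D^−α A D^−α), row normalization to a Markov operator, dense
     eigendecomposition through the symmetric similarity transform, removal
     of the trivial constant eigenvector, and automatic diffusion-time
     scaling of eigenvectors by λ/(1−λ). α = 0.5 and the λ/(1−λ) scaling
     are the conventional defaults for connectivity gradients.
   - *PCA*: scores of the column-centered matrix (left singular vectors ×
     singular values); eigenvalues are explained variances.
   - *Laplacian eigenmaps*: generalized problem L v = λ D v with
     L = D − A; the λ = 0 constant vector is dropped and components are
     ordered by ascending λ (most important first).

Deterministic orientation: every component is flipped so its
largest-|entry| parcel is positive (ties → lowest index). This removes the
eigenvector sign ambiguity *within* one extraction; sign and order
differences *across* subjects are deliberately left for alignment.
Components with eigenvalue below 1e−12 are rejected as degenerate;
disconnected affinity graphs raise an error advising lower sparsity.

## Procrustes alignment and diagnostics

The alignment is the closed-form orthogonal (Schönemann) solution:
C = (BᵀA)ᵀ = AᵀB, C = UΣVᵀ, T = UVᵀ, A′ = AT. No centering, no isotropic
scaling, and explicitly no iterative ("generalized") refinement — the
transform is a pure rotation/reflection of the gradient basis, so
‖A′‖_F = ‖A‖_F always. Rank-deficient C still yields a valid (non-unique)
T via the SVD; such cases are logged. SVD sign/order ambiguity under
repeated singular values resolves to LAPACK's deterministic convention.

Diagnostics reported per alignment:

- **correspondence** c = max|t_{i1}| / Σ|t_{i1}| ∈ [1/n, 1];
- **Trans_Total** = Σ|t_{ij}|, **Trans_PG** = Σ|t_{i1}|. Note these are
  heuristics: they are not monotone in the underlying rotation angle, a
  caveat we document rather than "fix";
- **‖w‖₂**, the ℓ₂-norm of the *raw* Procrustes singular values (w depends
  on gradient scaling, not only on subspace geometry);
- **‖Θ‖₂**, the ℓ₂-norm of the principal angles between the column spans,
  computed on orthonormalized (QR) bases as arccos of the singular values
  of Q_AᵀQ_B, clipped to [0, 1] (Björck–Golub definition). ‖Θ‖₂ = 0 iff the
  subspaces coincide; orthogonal subspaces give (π/2)√n. ‖w‖₂ and ‖Θ‖₂ are
  exposed separately because they answer different questions and are both
  reported by the study design.

The reversed cumulative sweep aligns component subsets
{K, K−1, …, K−c+1} (counting from the last extracted gradient downward)
and is emitted alongside the standard {1…c} sweep when requested.

## Motion metrics

- **FD**: Power-style framewise displacement — sum of absolute backward
  differences of the three translations (mm) plus the three rotations
  converted at a 50 mm head radius. FD is undefined at the first frame
  (set to 0, excluded from the session mean, and written as `n/a` in
  confounds files, the fMRIPrep dialect). If a confounds file already
  provides `framewise_displacement`, it is used verbatim.
- **TFC** = (1 + r(FC_subject, FC̄))/2, with r computed over the
  vectorized strictly-upper triangles (the constant diagonal would distort
  r) and FC̄ the Fisher-z group mean over the holdout subjects.
- **BOLD–FD correlations**: per parcel, Pearson r between frames 2…T of
  the BOLD series and the FD series (first frame dropped). For independent
  series the pooled null is centered at 0 with sd 1/√(T−3); constant
  parcels yield NaN and are excluded downstream.
- Fisher r-to-z at |r| ≥ 1 clips to ±(1 − 1e−7) with a logged warning,
  keeping group averages and z-variant identifiability totals finite.

## Identifiability

Identification accuracy matches each subject's aligned principal gradient
in session A against the session-B database by maximum Pearson
correlation; we compute both lookup directions and report their mean
(removing the arbitrary session-order dependence; ties break to the lowest
subject index with a logged warning). Differential identifiability
I_Diff = (I_self − I_other) × 100 averages the diagonal vs both
off-diagonal triangles of the cross-session correlation matrix; the
Fisher-z variant transforms every correlation first. The two variants can
trend in opposite directions — the z-variant weights gains in the high-r
regime much more strongly (atanh convexity), which is exactly why both are
reported.

## Nested cross-validated prediction

10 repetitions of 5-fold outer CV (stratified for classification); inner
5-fold grid search per outer training partition. Grids: ridge α ∈
geomspace(1e−3, 1e4, 50); SVM C ∈ geomspace(1e−4, 1e4, 10); RBF γ ∈
geomspace(1e−9, 1e4, 10); random-forest max_depth ∈ {5, 10, 20, None}.
Confound removal residualizes the *features* (per-feature OLS on the
confounds, intercept included), fit on outer-training rows only and applied
to both partitions — training residuals are exactly orthogonal to every
confound. Features are standardized inside the CV pipeline (switchable).
Identically-zero confound columns degrade gracefully to intercept-only
centering; genuinely rank-deficient confound designs raise. Median
binarization of FD assigns values equal to the median to the "low-motion"
class. Scores: out-of-sample R² (regression) or accuracy and ROC AUC
(classification); the summary sd is taken across the 10 per-repeat mean
scores. The inner selection criterion is the mean inner-fold score.

## Synthetic cohort: what it emulates

The generator produces the *relational* structure the analyses measure,
not realistic hemodynamics:

- A group basis (orthonormal P×K, geometric variance spectrum with ratio
  `eigen_decay`) shared by all subjects.
- A subject basis: a random P-space rotation of the group basis (matrix
  exponential of a random antisymmetric generator scaled to
  `subject_rotation_scale` spectral radians) composed with per-component
  sign flips and adjacent swaps (probability 0.3 each) — the
  indeterminacies Procrustes alignment exists to undo.
- Session noise: a K×K coefficient-space rotation
  (`session_rotation_scale`) mixing the subject's components. This
  emulates cross-session eigenvector instability — with a flat spectrum
  (`eigen_decay` = 0.95) adjacent components swap order easily — which is
  what makes the *number* of aligned gradients matter: one aligned
  gradient cannot recover a principal gradient that mixed into its
  neighbours, twenty can.
- Motion: per-subject mean FD ~ |N(`motion_location`, `motion_scale`)|
  (floored at 0.01 mm); a per-session rectified AR(1) FD trace (lag-0.6)
  rescaled to that mean; a motion-coupled rotation of magnitude
  `motion_coupling`·FD applied with weight `trailing_emphasis` inside the
  span of components 2…K and weight 1−`trailing_emphasis` across all of
  P-space; plus a BOLD artifact — the FD trace broadcast onto a random
  *session-specific* spatial map. The map must be session-specific: a
  session-stable artifact would itself be a subject fingerprint and invert
  the identifiability phenomenology.
- Time series: T×K unit-variance latent signals through the session basis
  (scaled by √(variance·P)) plus the artifact plus white noise
  (`noise_sd`). Latents are drawn per *subject*, so setting all
  session-variability knobs to zero reproduces identical sessions exactly.
- Phenotypes: an age-like variable positively coupled to the subject's
  latent motion level (r ≈ 0.4), and a score-like variable decreasing with
  age and carrying a gradient-loading term, plus noise. Magnitudes are
  configurable and not calibrated to any real dataset.

Defaults (60 subjects, 2 sessions, 100 parcels, 25 latent components, 400
frames, eigen_decay 0.95, subject/session rotation 1.0/0.8 rad, mean FD
0.15 ± 0.08 mm, motion_coupling 8, trailing_emphasis 0.8, noise 0.5) were
chosen so the generator sits robustly — across arbitrary seeds — in the
qualitative regime the analyses are designed to detect: identification
accuracy and z-variant differential identifiability rising with the number
of aligned gradients, correspondence falling, FD–diagnostic correlations
growing with the number of aligned gradients, and TFC negatively related
to transformation magnitude. What passing tests on this cohort show is
that the *pipeline* detects these structures when present and stays at
null when the couplings are switched off; they say nothing about effect
sizes in real fMRI, which depend on acquisition, denoising, and population
factors the generator does not model (no scanner physics, no hemodynamic
response, no parcellation error, no real spatial autocorrelation).

## Orchestration

The full study: read time series + confounds → FC → FD/TFC → seeded
holdout split (default 20 %, |holdout| = round(fraction·n)) → holdout
group-mean FC (Fisher-z pooled over all holdout sessions) → reference
gradients → per-subject extraction → alignment sweep (standard and
optionally reversed cumulative) → identifiability sweep over all session
pairs → motion-correlation sweep → prediction. Holdout subjects never
enter any analysis-stage table. Every output row carries kernel, sparsity,
approach, and seed provenance, and a JSON manifest makes reruns
byte-identical.

BH-FDR correction (step-up, q = 0.05) is applied per (motion metric,
diagnostic) family across the n_align values within each session — the
exact correction family is ambiguous in general, so it is recorded in the
output metadata; a cell is flagged "significant across all sessions" only
when every session survives. Correlation cells with a constant input are
excluded (logged) rather than reported as NaN.

Prediction inside the orchestrated run uses subject-level features (the
aligned principal gradient averaged across sessions), restricted by
default to n_align ∈ {5, 10, 20} and the ridge models to keep full runs
inexpensive; all models and any n_align subset can be requested in the
config. The problem sizes used by the test suite (cohorts of 10–60
subjects, 30–100 parcels) are the package's own desk-scale choices for the
synthetic study.

## Known limitations

- Trans_Total/Trans_PG are non-monotone descriptors of rotation size;
  interpret trends, not values.
- Eigenvalue-weighted Procrustes (weighting gradients by explained
  variance during alignment) is a plausible alternative but is not
  implemented — only the equal-weight orthogonal solution is.
- The generator's motion mechanism (trailing-component rotations plus a
  rank-one artifact) is one plausible emulation of how motion enters FC
  structure; only qualitative trends should be read from it.
- Laplacian-eigenmap "eigenvalues" are generalized Laplacian eigenvalues
  (ascending importance order), not explained variances; code consuming
  `GradientSet.eigenvalues` across methods must respect `method`.
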