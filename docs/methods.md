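# Methods

This note documents the models, parameter choices and numerical decisions
behind `morphoscreen`, and what the synthetic-data experiments do and do not
establish about real WSI cohorts.

## Synthetic cohort model

The generator is the package's ground-truth instrument, not a texture
simulator. Its design goal is that every downstream quantity has either a
closed form or a planted value.

**Nuclei.** Nuclei are non-overlapping ellipses (rejection-sampled
placement with a spacing margin; failure beyond a bounded retry count
raises, naming the density limit). Ellipses give exact oracles: area
`πab`, eccentricity `√(1 − b²/a²)`, solidity 1. Default semi-minor axis
3–6 px and aspect 1–2 emulate nucleus scale at ~20× patch resolution;
accuracy studies use larger shapes (semi-minor 10–18 px, aspect 1.3–2.2)
because moment eccentricity is ill-conditioned near the circle
(`de/d(b/a) → ∞` as `e → 0`) and rasterization error at 3–6 px exceeds any
useful tolerance.

**Staining.** Rendering inverts Beer–Lambert with a base-10 logarithm:
`I = I₀ · 10^(−W C)`, `I₀ = 255`, where `W` is a 3×2 unit-column stain
matrix (hematoxylin, eosin) and `C` the concentration field — the
per-nucleus HOD value inside nuclei, a low uniform eosin field (0.15 OD)
outside, and a small intra-nuclear eosin term (0.05 OD) so nucleus pixels
are honest two-stain mixtures. Per-slide matrices are Gaussian jitters
(sd 0.05 per component) of the canonical Ruifrok–Johnston H&E directions,
renormalized and rejected if the columns come within 5° of collinear.
Optional Gaussian OD noise and 8-bit quantization complete the forward
model. Pen marks are thick random polylines of a saturated color.

**Survival.** Hazard is `h₀(t)·exp(β_age·(age−μ) + β_age²·(age−μ)² +
β_subtype·s)` with exponential or Weibull baseline (`h₀` scaled so median
survival at the cohort mean is ~400 days, GBM-like). Ages are normal
(default mean 60, sd 10). Censoring is an independent coin flip at
`censor_rate` with the censoring time uniform on (0, T). The Weibull option
with shape ≠ 1 exists to build proportionality-violation scenarios from an
omitted covariate; the quadratic-age scenario below uses the exponential
baseline with a convex age effect instead.

**Per-index heterogeneity.** Within a patient, index values are iid draws
from the subtype's distribution (normal, lognormal, or a
mixture-of-lognormals option for multimodal within-slide heterogeneity —
the shape of real within-WSI variation is not observable at desk scale, so
it is configurable rather than asserted). The default planted contrast is
a one-sd mean shift in mean HOD between two subtypes.

What this does **not** emulate: tissue texture, vesicular chromatin,
segmentation errors correlated with phenotype, spatially structured
heterogeneity within a slide, or informative censoring. Passing tests
establish correctness of the computational chain and the statistical
behavior of the screen under the stated generative model — not performance
on real TCGA slides.

## Stain estimation and normalization

The estimator minimizes `‖OD − WH‖²_F + λ‖H‖₁` with `W, H ≥ 0` and
unit-norm columns of `W`, by exact block-coordinate descent:

* **H step.** With two stains the per-pixel subproblem is a 2-variable
  nonnegative least squares with an L1 shrink; its KKT solution is the best
  of three closed-form candidates (interior point, two single-stain faces),
  solved vectorized for all pixels.
* **W step.** With unit-norm columns, `‖w h‖²_F = ‖h‖²` is constant, so the
  optimal column given everything else is the normalized nonnegative
  clip of the residual-weighted direction `R hᵀ`. Each step is an exact
  minimizer, so the objective is non-increasing by construction (asserted
  per iteration in tests); convergence is typically < 30 iterations.

`λ` is relative: the effective penalty is `λ · mean(OD)` (default λ =
0.01), so sparsity pressure is independent of overall stain strength and
small enough not to bias the HOD readout. Initialization uses the nucleus
mask — column 0 from the mean OD direction of mask-interior pixels, column
1 from exterior tissue pixels — which both speeds convergence and pins the
hematoxylin/eosin ordering; degenerate masks (empty, all-covering) fall
back to principal OD directions and flag the estimate. Final ordering
takes the channel with the larger mean intra-nuclear concentration as
hematoxylin, tie-broken by the larger blue-channel OD loading.

Normalization rescales concentrations by `target_max / source_reference`
per channel with the source reference at the 99th concentration percentile
(robust to outlier pixels; the paper-scale alternative — a literal maximum
— is one config value away), then re-renders through the target matrix.
Patches with fewer than 100 informative pixels (OD magnitude > 0.05) are
flagged low-tissue and excluded from features.

A known identifiability limit: with intra-nuclear eosin co-expression, the
"hematoxylin" cone edge of the data is a mixture ray, so recovered columns
agree with truth to cosine ~0.999 rather than exactly, and cross-slide HOD
agreement is ~1% rather than 0. The exactness tests therefore render
without intra-nuclear eosin; the invariance tests keep it.

## Morphometry

* **Eccentricity** from central second moments (ellipse-equivalent).
* **Solidity** is pixel count over the area of the convex hull of the
  pixel *centers*, clipped at 1. A pixelated hull (extra boundary ring)
  systematically depresses solidity of small convex nuclei to ~0.92–0.96,
  which would swamp the pleomorphism signal; the point-sample hull scores
  convex shapes ~1 and agrees with the exact union-of-squares hull within
  0.02 on concave shapes (the cross-shape oracle value is 5/7 — the hull
  of a plus is an octagon).
* **Cellularity** is `1 / mean(incident Delaunay edge length)` per nucleus,
  with edges above 100 px excluded to suppress convex-hull boundary
  artifacts. The statistic is exact on lattices (hexagonal spacing d →
  interior value 1/d), scale-equivariant, and monotone in density. The
  per-patch nucleus count is available as an alternative density measure
  via configuration; the per-nucleus form is the default because it can
  enter the PDF representation.
* Border-touching nuclei are flagged and excluded from per-patch medians
  (truncated areas would bias them); patches with fewer than 5 usable
  nuclei contribute no profile.

## Heterogeneity representations

**Patient PDFs** use 64 equal-width bins spanning the cohort's 0.5–99.5
percentile range (outliers clip into the end bins). 64 bins balance EMD
resolution against per-patient support; patients with under 50 nuclei are
flagged low-support. The 1-D EMD closed form (CDF L1 distance × bin width)
is the production distance; a dense LP oracle lives in the tests.

**Dictionaries** run k-means 10 times on subsamples of up to 1000 patch
profiles with Gaussian noise injected at 5% of each feature's sd — the
perturbation that separates stable clusters from fragile ones. Repeat
centroids are matched to the first repeat by optimal assignment
(Hungarian), aggregated by componentwise median, and ordered ascending so
"cluster 0" is always the low end of the index. The consensus matrix is
the co-assignment frequency over repeats for pairs sampled together
(never-co-sampled pairs fall back to final-assignment agreement). Noise is
added to features rather than only to the subsampling; the subsample-only
variant is the obvious alternative and differs only for knife-edge
clusters. Model selection reports the consensus-CDF curve and its AUC
increment per k alongside the mean silhouette (computed on a capped random
subsample, cap 800,000); the recommended k maximizes silhouette.

## Survival screen

All biomarker tests are likelihood-ratio tests of nested Cox models,
`age + age²` versus `age + age² + representation`, with Efron tie
handling. Age is centered before squaring to reduce collinearity; hazard
ratios and all test statistics are invariant to the centering. PDF cluster
labels enter as dummies against the lowest-labeled cluster; dictionary
signatures enter as continuous compositional components with the first
dropped; the combined model carries both (df = sum of added parameters).
Patients with non-positive survival time are dropped; categorical levels
with zero events are non-estimable and are excluded and flagged rather
than aborting the screen; a covariate that collapses to the null (zero
variance) yields LRT statistic 0 with p = 1.

Proportionality is checked by scaled Schoenfeld residuals against
rank-transformed event time, per covariate, with an omnibus statistic
formed by summing the per-covariate chi-squares (df = number of
covariates) — a standard approximation rather than the joint score test.
Significant screens get Wald 95% CIs per level and pairwise Wald contrasts
from the full covariance matrix; the pairwise test between levels i and j
equals the Wald test of level j after re-referencing to level i (asserted
against a refit in tests).

The screen reports raw p-values per index × representation × k, matching a
one-test-per-row screening table; a Benjamini–Hochberg column is emitted
alongside but is not the headline criterion. Preconditioned screens
(genomic subtype, EGFR high/low by 1-D linkage on expression) refilter the
cohort and rebuild bins, dictionaries and distances on the subcohort;
subcohorts under 20 patients or 10 events are skipped with the reason
recorded.

**Why age², concretely.** Under a convex age-log-hazard (simulation:
n = 300, ages N(60, 13), β_age = 0.05/yr, β_age² = 0.005/yr² on centered
age, no censoring), the age-only model's Schoenfeld test flags
non-proportionality in ~82% of replicates; adding age² drops that to ~2%
and restores LRT calibration. The companion confounding guard: when
cluster labels are age tertiles with no independent effect, the unadjusted
logrank rejects almost always while the age-adjusted LRT stays at the
nominal 5%.

**Combined-model dilution.** When signal lives in one representation only,
the combined model spends extra degrees of freedom on the uninformative
one; its p-value is usually (not always) larger than the single-
representation p, but detection power at realistic effect sizes remains
high (asserted ≥ 80% in tests). Both representations agreeing on an index
is the stability argument for reporting it.

## Pipeline and determinism

The orchestrated run executes simulate → preprocess (background filter,
pen-mark SVM trained on clean patches paired with pen-marked copies of
themselves) → stain normalization and HOD → morphometry → representations
→ screen, writing TSV/JSON outputs under a seed-named directory with a
manifest that balances `patches_in = kept + background + penmark +
low_tissue`. All randomness flows from the config seed through
`numpy.random.default_rng`; k-means, the SVM split and noise injection are
all seeded, and two runs with the same config are byte-identical. The
shipped default exercises the full chain on 30 patients × 4 patches —
small enough to run in seconds per stage while every filter and screen
path executes.

## Known limitations

* The baseline watershed segmenter stands in for a trained network; it is
  adequate on rendered ellipses (peak detection on a smoothed distance
  transform; elongated nuclei are the failure mode it smooths over) but is
  not a contribution, and any external mask supplier can replace it.
* Eccentricity of near-circular nuclei is intrinsically noisy at nucleus
  scale; cohort-level eccentricity contrasts are meaningful, individual
  near-zero values are not.
* The EMD/linkage path treats one index at a time by design (interpretable
  single-index biomarkers); joint-index transport is out of scope.
* Statistical behavior is verified under the generator's assumptions
  (independent patients, exponential/Weibull baselines, iid within-patient
  draws); real-cohort violations — informative censoring, within-slide
  spatial correlation, segmentation bias — are untested here.
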