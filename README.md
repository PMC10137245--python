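# morphoscreen

Nuclear-morphometry tumor-heterogeneity biomarker screening for H&E-stained
whole-slide-image (WSI) cohorts, with a synthetic-cohort generator so every
stage is testable at desk scale.

## The problem

Glioblastoma multiforme (GBM) slides are heterogeneous — nuclear size,
chromatin content and cell packing vary within and between patients — and
the cohorts that carry survival annotation (e.g. TCGA) add two obstacles on
top of the biology:

1. **Technical variation.** Staining differs slide to slide, so hematoxylin
   optical density (HOD, the chromatin surrogate) is not comparable across
   patients without normalization; pen marks and background tiles
   contaminate the tiles.
2. **Age confounding.** Age is the strongest predictor of GBM outcome, and
   its effect is nonlinear: a Cox model with age alone violates the
   proportional-hazards assumption, and a screen that ignores age credits
   any index that merely tracks it.

`morphoscreen` implements the whole chain: tile filtering, sparse-NMF stain
normalization, per-nucleus morphometry, two heterogeneity representations,
optimal-transport subtyping, and an age-adjusted likelihood-ratio screen.

## The method

For each morphometric index *x* (area, eccentricity, solidity, mean/total
HOD, Delaunay cellularity):

* **Stain model.** Each patch's optical density is factorized as
  `OD ≈ W H`, `W ∈ R^{3×2}` (unit-norm hematoxylin/eosin columns),
  `H ≥ 0`, minimizing `‖OD − WH‖²_F + λ‖H‖₁`; the nucleus mask initializes
  `W` and fixes the channel order. Concentrations are mapped to a common
  target stain, after which `H₁` per nucleus is the HOD readout.
* **Patient PDF.** The patient's nucleus values histogrammed on cohort-wide
  bins; patients are compared by the 1-Wasserstein (earth-mover) distance
  `EMD(p,q) = Σ_b |F_p(b) − F_q(b)| Δ` and clustered by average linkage.
* **Dictionary.** Per-patch medians pooled over the cohort are clustered by
  subsampled, noise-injected consensus k-means (k ∈ {2,3,4}, chosen by
  silhouette with consensus-CDF diagnostics); each patient becomes the
  frequency vector of the learned alphabets.
* **Screen.** For each representation the likelihood-ratio test compares
  nested Cox models `h₀(t)·exp(β₁ age + β₂ age²)` versus the same plus the
  index representation; proportionality is checked with scaled Schoenfeld
  residuals, and significant hits get 95% hazard-ratio CIs and pairwise
  Wald contrasts. A combined model carries both representations at once,
  and the screen can be preconditioned on genomic subtype or EGFR
  high/low strata.

## Worked example

`examples/` contains one narrative script per capability. For instance,
stain normalization (`python examples/02_stain_normalization.py`) renders
the same nuclei under two different stain matrices, estimates each by
sparse NMF and maps both to the common target:

```
slide A: stain-column cosines to truth = 0.9993, 1.0000
slide B: stain-column cosines to truth = 0.9996, 1.0000
max relative HOD difference across slides after normalization: 0.007
```

Cosines near 1 mean the NMF recovered each slide's true stain directions;
after normalization the per-nucleus chromatin readout differs by under 1%
between slides — the property that makes HOD usable as a biomarker.

The screen (`python examples/05_survival_screen.py`) plants a survival
effect in mean HOD and none in eccentricity, then prints the
likelihood-ratio p-value per index × representation × k:

```
       index representation  k  p_lrt  ph_global_p     n
    mean_hod            pdf  2 0.0000       0.2814 100.0
    mean_hod           dict  2 0.0000       0.2517 100.0
    mean_hod       combined  2 0.0000       0.1227 100.0
    mean_hod           dict  3 0.0000       0.4384 100.0
eccentricity            pdf  2 0.5733       0.1733 100.0
...
significant rows (p < 0.05): 4 — indices: ['mean_hod']
```

Only the index that carries the planted effect fires.

The full pipeline (simulate → filter → normalize → features → screen) runs
from a config: `morphoscreen --seed 7 --out runs/` writes the clinical
table, the patch keep-list, the per-nucleus feature table, the screen table
and a manifest with filter accounting under `runs/seed_7/`.

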