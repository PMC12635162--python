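# Methods

This note documents the models, numerical choices and limitations of
the `pnms` package in enough detail to audit or extend it.

## Phantom cohort

The synthetic cohort stands in for a 30-patient mTLE series treated
with laser ablation. Each subject is a 48×48×48 lattice of 2 mm voxels
(even x-dimension, so the midsagittal plane is the exact lattice
midplane and flipping is an index reversal). Geometry: an ellipsoidal
brain with a gray-matter shell, white-matter core and mirrored
ventricular CSF; spherical hippocampi (radius 5 voxels) and amygdalae
(radius 3) at mirrored coordinates, carved out of white matter as gray
matter. Modalities are piecewise-constant tissue mixtures (PET:
GM 1.0 / WM 0.5 / CSF 0.05; FLAIR: 0.8 / 1.0 / 0.3; T1 GM density:
the GM fraction) plus additive Gaussian voxel noise (SD 0.05) applied
after effect insertion, matching the standardized-intensity scale the
pipeline operates on.

Planted disease effects, all on the side of the epileptogenic zone:

* **Hypometabolism** — PET is multiplied by (1 − d·profile), where the
  profile is 1 inside the hippocampal sphere and rolls off as a
  Gaussian (σ = 0.35 r) outside it. With the contralateral side
  unaffected, the noiseless AI at a fully affected voxel is
  −2d/(2−d); the default peak depth d = 0.20 gives AI = −0.2222.
* **Atrophy** — the T1 GM density is reduced by the same profile scaled
  to the atrophy fraction (default 0.15), and the hippocampal label is
  eroded by the matching radius factor (1−a)^{1/3}, so both density
  and label-derived volumetry register the loss. Depth and atrophy are
  drawn per subject as correlated Gaussians (r = 0.5), the planted
  structure–function coupling.
* **Ablation cavity** — the "true" hypometabolic region is the set of
  voxels whose noiseless AI falls at or below the planted threshold
  (default −0.06). The cavity covers a Beta(2, 1.5)-distributed
  fraction of that region (the source cohort's coverage distribution
  is unpublished, so it is a parameter), growing from an entry point
  offset 1.5 r from the hippocampal centre in a random direction — a
  laser-trajectory-like geometry that leaves a coherent remnant and
  spreads the in-ROI ablative rate across subjects.
* **Outcome** — seizure freedom ~ Bernoulli(expit(α + β·coverage)),
  β = 6 by default; α is solved per cohort (Brent's method) so the
  expected seizure-free fraction equals the 0.70 prevalence target.
  Over 1000 simulated cohorts of n = 30 the mean seizure-free fraction
  stays within ±0.02 of 0.70 (tested).

Everything is deterministic given (cohort seed, subject seed); integer
masks reproduce bitwise. A global head-size factor (SD 4%) varies TIV.
The generator makes no attempt at MRI physics, scanner artifacts,
registration error or anatomically shaped structures; passing tests
demonstrate the statistical machinery, not robustness to real-data
artifacts such as segmentation error or imperfect midsagittal
alignment.

## Preprocessing

Default stage order per modality: smooth (6 mm FWHM Gaussian,
σ = FWHM/(2√(2 ln 2))/voxel, reflective boundaries, which conserve
total intensity) → Müller–Gärtner PVC (PET only) → standardize →
AI map. The order is configurable and recorded in the run config; the
default follows the acquisition-style convention of resolution
correction before intensity normalization. Standardization uses the
sample SD (ddof = 1); proportional scaling to a fixed mean is available
as an alternative normalization.

MG PVC reference activities μ_WM and μ_CSF are means over voxels with
compartment probability ≥ 0.9 after one binary erosion (falling back to
the uneroded core, then to 0 for an absent compartment). The corrected
image is only defined where the smoothed GM map ≥ `gm_floor` (default
0.3); other voxels are NaN and leave the mask rather than amplifying
noise. On a noiseless piecewise-constant phantom blurred once by the
6 mm PSF, the GM core (GM ≥ 0.99 eroded by 3 voxels ≈ one PSF width) is
recovered within 2% (tested; the bound degrades within one PSF width of
tissue boundaries).

The AI formula presumes nonnegative intensities; standardized images
are not. The pipeline therefore computes AI on positively shifted
copies — the image is offset so the within-mask minimum equals 1% of
the range — preserving left–right ordering and restoring the [−2, 2]
bound and flip-antisymmetry (both hold to 1e-12 on every phantom,
tested). The shift is recorded in the map's metadata; the AI scale then
depends on the shift, so AI values are comparable within a
configuration, not across shift conventions. Voxels with
|denominator| < eps (default 1e-6) or outside mask ∩ flip(mask) are
invalid and excluded downstream.

## Statistics

* **RCS logistic regression.** Harrell's restricted basis with
  (t₃−t₁)² normalization, knots at type-7 (linear-interpolation)
  quantiles 10/50/90%. Nonlinearity is a 1-df likelihood-ratio test of
  the spline column (LR, not Wald, for small-n behaviour); the overall
  predictor test is 2-df. Model choice between spline and linear is by
  BIC = −2ℓ + k ln n, ties to fewer parameters. Curves are evaluated
  on a 200-point grid over the predictor's [2.5, 97.5] percentile
  range with covariates at their means; ORs are referenced at the
  median (OR = 1 there by construction), CIs by the delta method.
* **Inflection points.** Sign changes of the first difference of the
  fitted log-odds grid are interior extrema (U/N shapes). A monotone
  curve gets the curvature elbow (max |second difference|), labelled
  "elbow" and shaped "L" when one arm is ≥ 4× flatter than the other.
  Identifiability differs sharply: planted direction-changing links
  are recovered within ±0.02 in ≥ 90% of seeded cohorts (n = 500),
  while pure elbows of L-shaped links are much less identifiable
  (~25% at the same tolerance) — the elbow of a smooth spline fit is
  only loosely pinned to the kink. The threshold-cohort simulator
  therefore defaults to a direction-changing ("vee") link; the
  L-shaped link remains available for sensitivity analyses.
* **ROC/Youden.** Candidate cutoffs are midpoints between consecutive
  sorted unique scores plus sentinels; positive means score ≥ cutoff.
  J = sens + spec − 1 is maximized, ties to the lower cutoff; AUC is
  the trapezoid over the empirical ROC traversed in descending cutoff
  order. Balanced accuracy is (sens+spec)/2; the prevalence-weighted
  accuracy w·sens + (1−w)·spec with class-prevalence weights equals
  the overall accuracy (tp+tn)/n. Both are reported because they
  answer different questions under class imbalance (at 21/9 and
  sens 0.95 / spec 0.56 they are 0.75 and 0.83 respectively).
* **Categorical tests.** Pearson χ² is uncorrected by default (Yates
  optional); likelihood-ratio G², Fisher exact, pooled/Welch t,
  Mann–Whitney, one-covariate ANCOVA (linear-model F) and Pearson r
  wrap scipy/statsmodels. All tests two-sided at α = 0.05 with no
  multiplicity correction.
* **Odds ratios** are reported per configurable predictor unit
  (default 0.01 AI units for asymmetry features) and the scale is
  echoed in the output, never left implicit.

## Interpretation model

The "GAM" is an unpenalized Gaussian additive model: intercept plus one
3-knot restricted-spline smooth (2 columns) per feature, least-squares
fit — the smallest model class consistent with an additive smooth model
that is exactly reproducible with no smoothing-parameter search at
n = 30. Features with fewer than 10 distinct values fall back to a
linear term. Rank deficiency raises with the offending feature named,
except inside Shapley payoffs where the minimum-norm solution is used
(predictions are projections and remain unique under collinearity).

Shapley values use the retrain-per-subset payoff with exact enumeration
of all 2⁵ feature subsets (capped at 12 features); the empty coalition
predicts the target mean. Efficiency, symmetry and null-player hold by
construction (tested to 1e-8). The reported "feature weight" is the
signed per-feature mean across subjects; the mean |value| is used for
ranking, since signed means of centred effects hover near zero.

Repeated 5-fold cross-validation re-partitions each of the (default)
1000 iterations with a seeded generator; per-subject predictions are
across-iteration means with 2.5/97.5-percentile intervals. At n = 30
with 11 parameters the out-of-fold fit is deliberately honest about
overfitting: the actual-vs-predicted Pearson r attenuates relative to
the in-sample fit, and with a planted structure–AI coupling of r ≈ 0.5
the two-sided significance test has power ≈ 0.78, so a minority of
seeded cohorts legitimately fail to reach P < 0.05.

## Determinism and outputs

All randomness flows from explicit seeds through
`numpy.random.default_rng`; re-running a configuration reproduces every
numeric output byte for byte (tested end to end). Runs write
`report.json`, tidy CSVs (features, RCS curves, CV predictions, Shapley
values, partial dependence) and the resolved YAML config whose hash
(excluding output paths) names the analysis.

## Known limitations

* Phantoms are geometric, not anatomical; AI magnitudes after
  standardize+shift are configuration-dependent and not directly
  comparable to raw-intensity AI thresholds.
* The elbow fallback for L-shaped curves is weakly identified (above).
* Real data must arrive already aligned in a left-right symmetric
  space; registration, segmentation and template construction are out
  of scope.
* The unpenalized additive model is limited to small feature counts;
  no penalized smoothing or sampling-based Shapley approximation is
  provided.
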