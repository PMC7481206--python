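# Methods

## Scope and data model

The package operates downstream of image acquisition and registration: it
assumes co-registered pre/post-contrast T1-weighted volumes and an ADC map
on a shared grid (NIfTI-1, voxel spacing in mm). Computing ADC from raw
diffusion-weighted acquisitions, affine registration, skull stripping and
DICOM ingestion are out of scope. The canonical ADC unit is µm²/ms
(1 µm²/ms = 10⁻³ mm²/s); maps stored in mm²/s are converted on load and the
source unit recorded. NIfTI headers carry no diffusivity unit, so the unit
must be supplied explicitly or via a JSON sidecar — a silent guess would be
a factor-of-1000 error.

## Enhancement segmentation

Both T1 volumes are intensity-normalized by z-scoring within the brain mask
(mean 0, sample SD 1, n−1 denominator; voxels outside the mask set to 0).
The normalization transform is a design choice: "positive subtraction
values" is only meaningful on a common intensity scale, and z-scoring is the
simplest transform that provides one while being invariant to positive
affine rescaling of either input. The enhancement mask is the set of voxels
where normalized post − normalized pre is strictly > 0, restricted to the
brain mask, with 26-connected components smaller than
`min_component_voxels` (default 10) removed to suppress salt noise.
Measurable disease is defined in-plane: some axial slice (third array axis)
whose bounding box reaches 10 mm in both in-plane directions.

## ADC histogram model

ROI ADC values are binned into 128 equal-width bins over [0, 4] µm²/ms
(density-normalized; out-of-range voxels are counted and logged, and fits
are refused below 100 in-range voxels). The two-component model

p(ADC) = f·N(µ_L, σ_L) + (1 − f)·N(µ_H, σ_H)

is fitted to the histogram density by unweighted nonlinear least squares
(trust-region reflective, bounds f ∈ [0.01, 0.99], σ ∈ [0.01, 2.0] µm²/ms,
µ inside the histogram range). Initialization is multi-start (default 8,
deterministic given the seed): µ_L from the 20th–40th weighted percentile
of the histogram, µ_H from the 60th–80th, σ from IQR/2 × {0.5, 1}, f = 0.5;
the best start by residual sum of squares wins, and components are
relabeled so µ_L ≤ µ_H. Optimizer failure is reported through
`converged=False`, never an exception.

Binning and objective details (bin count, counts vs density, weighting) are
free choices here; the suite verifies the fitted µ_L moves by less than
0.02 µm²/ms between 64 and 256 bins on 50k-voxel samples, so the default is
not load-bearing.

Degeneracy: a fit with f ≤ 0.02, f ≥ 0.98 or |µ_H − µ_L| < 0.05 is flagged
degenerate and still reported. When the weight is extreme the vestigial
component is a noise artifact chasing a histogram tail, and its mean is not
a meaningful ADC_L; the fit therefore collapses to a single-Gaussian
least-squares refit whose mean both components share (f reported as 0.5).
This keeps the reported ADC_L within sampling error of the true mean on
single-Gaussian input instead of returning an arbitrary tail location.

Phenotype: "high" iff ADC_L strictly exceeds the threshold (default
1.24 µm²/ms); equality is "low".

## Probability index and biopsy targets

The per-voxel index I(x) (see README) is evaluated in closed form via the
Gaussian CDF; adaptive quadrature of the defining integrals is retained
only as a test oracle. Three deliberate conventions: the mixture weight f
does not enter the index (an optional `weighted=True` variant exists for
exploration and is never used in shipped results); the lower bound 0 of the
pdf_H integral is honored exactly with untruncated Gaussians; and when both
tail masses underflow (possible in the gap between very separated
components) the sign-consistent limit ±1 is returned with a logged warning,
the sign decided in log space. The index is monotone non-increasing in x,
tends to 1 as x → 0⁺ and to −1 as x → ∞. Outside the ROI the map is NaN,
documented as "undefined", and never serialized as a number.

Targets are cubes of edge round(5 mm / voxel size) voxels per axis (minimum
1). A cube is admissible when every voxel lies inside the ROI, outside the
caller-supplied exclusion mask (eloquent cortex, vasculature — no atlas is
bundled), and disjoint from previously selected cubes. Selection is greedy
per pair: the admissible cube with maximal mean index (the low-ADC
target — highest probability of the lower distribution) then the one with
minimal mean index; ties break to the lexicographically smallest cube
origin so runs are deterministic. How a surgeon would place targets within
high/low regions is operator judgment; greedy mean-index optimization is
this package's operationalization of it.

## Cohort statistics

Pearson correlation reports r, R² and the two-sided p from the t transform
with n−2 df. The unpaired t-test pools variances (classic Student's; Welch
via `equal_var=False`); the paired test operates on differences and rejects
all-zero difference vectors. Z-scoring always uses the n−1 SD. Median
splits label "high" only strictly above the median, mirroring the strict
ADC_L rule. Kaplan–Meier estimation and the two-group log-rank test
(chi-square, 1 df) come from lifelines; the survival median is the first
time the product-limit estimate falls to ≤ 0.5 and is serialized as null
when the curve never does. Multi-site biopsy tables are z-scored within
tumor before pooling, and the paired intratumoral contrast compares each
tumor's mean expression at high-ADC_L sites vs low-ADC_L sites (within-
tumor median split). No multiple-testing correction is applied anywhere —
each reported p is marginal, and the report should be read accordingly.

## Synthetic data: what it emulates, and what it does not

The generator produces exactly the statistical structure the analysis
assumes:

* **ROI voxels** drawn from the two-Gaussian mixture (per-subject truth
  retained for every test);
* **anatomy**: an ellipsoidal lesion on a shared background field, the
  post-contrast volume equal to the pre-contrast volume plus a constant
  enhancement (2 signal units) inside the lesion. The background spatial SD
  is 5 units; keeping the enhancement below it matters, because z-score
  renormalization of the post volume slightly rescales the background, and
  the analytic margin before any background voxel flips positive is
  E·v·s/(s₂−s₁) ≈ 5.4 background SDs for the default 32³ grid and radius-8
  lesion (E enhancement, v lesion volume fraction, s background SD). With
  that margin the subtraction recovers the lesion essentially exactly, so
  segmentation failures in tests indicate real defects. Background ADC is
  N(0.7, 0.05) µm²/ms, well below the lesion mixture.
* **cohorts**: per subject a true ADC_L uniform on (0.31, 2.2) µm²/ms
  (matching a reported recurrent-glioblastoma cohort whose mean ADC_L was
  1.24 with that range); expression = intercept + slope·ADC_L + N(0, σ)
  with defaults slope 1.0, σ 0.67 — population R² ≈ 0.4, the order of the
  reported imaging–expression correlations; survival exponential with
  rate ln 2 / median so stated group medians (defaults 9.33 months above
  the 1.24 threshold, 5.87 below, a cohort of 172) hold in closed form;
  independent right censoring with probability 0.15 (not reported in the
  source cohorts; fixed once here), the censoring time drawn uniformly on
  (0, T). One integer seed drives a cohort; per-subject sub-streams derive
  deterministically from it.

Not emulated: MRI physics (Rician noise, bias fields, partial volume),
multi-scanner heterogeneity, non-ellipsoidal lesion geometry, non-linear
expression coupling, non-proportional hazards. Passing tests therefore
demonstrate correctness of the estimators and pipeline plumbing under the
model's own assumptions, not robustness to real-world acquisition effects.

## Numerical and testing choices

Problem sizes in the test suite are chosen to make sampling error small
relative to the asserted tolerances while keeping the default run short:
parameter recovery uses 50 subjects at ~10,000 ROI voxels (median
|µ̂_L − µ_L| ≤ 0.03 µm²/ms asserted, with an independent EM fit of the raw
voxels agreeing within 0.02 on µ_L and 0.05 on f); segmentation fidelity
uses 20 seeds (Dice ≥ 0.9 asserted; observed 1.0); calibration suites use
500 null replicates with the acceptance band [0.03, 0.07] for the observed
type-I rate at α = 0.05; null-cohort runs use 100 seeds. The end-to-end
phenotype-call check places true ADC_L values on a fixed grid excluding a
±0.1 µm²/ms band around the 1.24 threshold: at ~2,000 ROI voxels the
estimator's sampling error makes calls inside that band unresolvable in
principle, so including them would test the random number generator, not
the pipeline.

## Known limitations

Two-component mixtures only; histograms with genuinely more modes will be
summarized by their best two-Gaussian approximation. The probability index
follows its printed definition and ignores f, so it is a likelihood-ratio-
style contrast of component memberships, not a posterior probability.
Survival tooling is two-group Kaplan–Meier/log-rank only — no Cox or
multivariable adjustment. Exclusion masks are caller-supplied; the package
knows nothing about eloquent anatomy.
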