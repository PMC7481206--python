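# adchist

Quantitative diffusion-MRI analysis of contrast-enhancing brain tumors
(glioblastoma in particular): extract the enhancing region of interest by
normalized T1 subtraction, model the region's apparent diffusion coefficient
(ADC) histogram as a two-component Gaussian mixture, derive the ADC_L imaging
phenotype, compute voxel-wise probability maps for image-guided biopsy
targeting, and run the cohort association layer linking the phenotype to
molecular expression and survival. A synthetic-data generator makes every
stage testable without patient data.

Intended users are imaging scientists and neuro-oncology researchers working
with co-registered pre/post-contrast T1-weighted volumes and ADC maps
(NIfTI-1), plus subject-level tables of expression and survival.

## The model

ADC values inside the enhancing ROI are treated as draws from

```
p(ADC) = f · N(µ_L, σ_L) + (1 − f) · N(µ_H, σ_H)
```

fitted to the ROI's density-normalized histogram by nonlinear least squares.
**ADC_L = µ_L**, the mean of the lower Gaussian (µm²/ms), is the phenotype
variable: tumors with ADC_L strictly above 1.24 µm²/ms are "high", the rest
"low".

Each ROI voxel with ADC value *x* is then scored with the probability index

```
I(x) = [ ∫ₓ^∞ pdf_L − ∫₀ˣ pdf_H ] / [ ∫ₓ^∞ pdf_L + ∫₀ˣ pdf_H ]   ∈ [−1, 1]
```

where pdf_L and pdf_H are the component densities (the mixture weight f does
not enter). I = 1 means the voxel certainly belongs to the lower
distribution. Both integrals are evaluated in closed form through the
Gaussian CDF. Biopsy targets are 5 mm cubes chosen greedily on this map: the
admissible cube maximizing the mean index and the one minimizing it, kept
disjoint, per requested pair.

The association layer provides Pearson correlation of expression vs ADC_L,
pooled-variance t-tests between phenotype groups, within-tumor z-scoring for
multi-site biopsy tables, median-split stratification, and Kaplan–Meier
survival with the two-group log-rank test.

## Worked example

Generate a synthetic subject with known mixture truth
(f = 0.6, µ_L = 1.31, σ_L = 0.15, µ_H = 2.2, σ_H = 0.25 µm²/ms), then run the
full pipeline from a config file:

```python
from adchist import MixtureSpec, make_subject_volume
from adchist.synthetic import write_subject

spec = MixtureSpec(f=0.6, mu_L=1.31, sigma_L=0.15, mu_H=2.2, sigma_H=0.25)
write_subject(make_subject_volume(spec, seed=7), "demo/subject")
```

```
$ adchist run --config demo/config.yaml
phenotype high (ADC_L = 1.308 µm²/ms); outputs in demo/out
```

The fitted parameters land on the generating truth — `demo/out/fit.json`:

```json
{
  "f": 0.6057179204598405,
  "mu_L": 1.308185891751308,
  "sigma_L": 0.1553589482667566,
  "mu_H": 2.1916091055185243,
  "sigma_H": 0.2444472001980313,
  "converged": true,
  "degenerate": false
}
```

ADC_L = 1.308 > 1.24, so the tumor is called a high-ADC_L phenotype. The
selected 5-mm biopsy targets (`demo/out/targets.json`) are one low-ADC-
distribution target (highest mean index, here 0.336 — the cube most likely
to sample lower-diffusivity tissue) and one high-ADC target (lowest mean
index), with centers in voxel and world coordinates. The output directory
also holds the enhancement mask, histogram CSV, probability map (NaN outside
the ROI) and a manifest with input checksums, the config hash and seeds.

For a cohort-level run:

```
$ adchist simulate --out sim --n-subjects 40 --seed 1
$ adchist stats --table sim/cohort.csv --out sim/stats
```

which prints the association report (correlation R² and p, group means and
t-test, Kaplan–Meier medians and log-rank p per stratification) and writes
it with scatter/KM plots under `sim/stats/`.

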