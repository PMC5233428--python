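# irlfod

Spherical deconvolution of diffusion-weighted MRI with an **explicit
isotropic compartment**, an over-complete dictionary representation of the
fiber orientation distribution function (fODF), and a multiplicative
Richardson–Lucy (ISRA-type) solver with spatial TV and ℓ1 regularization.

## The problem

In diffusion MRI, partial volume effects — gray matter and CSF mixing into
white-matter voxels, or genuinely dispersed microstructure — contaminate the
anisotropic signal that spherical deconvolution uses to estimate fiber
orientations. Ignoring the isotropic part inflates angular errors and
produces spurious fODF peaks, especially at low SNR and small crossing
angles. This package is for researchers working with single-shell HARDI
phantoms or in-vivo data who want crossing-fiber orientations *and* a
per-voxel isotropy index from the same fit.

## The model

Per voxel, the attenuation signal is modeled as

```
S = R̂ f,     R̂ = [R_ani  R_iso],      f = Φ c = [f_ani, f_iso]
```

* `R_ani[i, j] = exp(−b_i · 3MD · (g_i·v_j)²)` — the maximally anisotropic
  (FA = 1) single-fiber response along each of J = 321 hemisphere sampling
  directions, with MD = 0.7 × 10⁻³ mm²/s;
* `R_iso = exp(−b · MD)` — the isotropic (FA = 0) compartment with the same
  mean diffusivity;
* `Φ` — a block-diagonal dictionary of L ≥ J antipodally symmetric
  double-lobe kernels `d(v, u_l) = κ₁ |cos ϑ|^τ` that maps nonnegative
  coefficients `c = [c_ani, c_iso]` to the fODF. The b = 0 rows (all ones)
  stay in the operator: they pin the total compartment volume, which is what
  makes an isotropic compartment identifiable from a dispersed spread of
  sticks on single-shell data.

The coefficients are fitted by the multiplicative iteration

```
c ← c ⊙ (Aᵀ S) ⊘ (Aᵀ A c) ⊙ L1 ⊙ TV,       A = R̂ Φ,
```

with per-channel spatial total-variation factors
`1/(1 − λ_TV div(∇c/|∇c|_ε))` and ℓ1 shrinkage `1/(1 + λ_ℓ1)`
(defaults λ_TV = 0.5, λ_ℓ1 = 0.01, 200 iterations). Nonnegativity is
automatic; the fixed iteration cap guards against the semi-convergence of
RL-type deconvolution under noise.

Outputs per voxel: fODF samples on a 10 242-vertex sphere, extracted peaks,
and scalar indices — the isotropy index **P_iso = c_iso / Σc** (low in
coherent white matter, high in gray matter/CSF), GFA, GRA, and tensor FA.
Evaluation against phantom ground truth uses the average angular error (AAE)
of matched peaks and over/under-estimated peak rates (r⁺, r⁻), with a
match limit of half the crossing angle capped at 35°.

## Worked example

Fit a noisy two-fiber phantom patch (70° crossing, 50% isotropic signal,
b = 3000 s/mm², SNR 20, 121 voxels) and score it against ground truth:

```python
import numpy as np
import irlfod as F
from irlfod.phantom import crossing_directions

gtab = F.default_gradient_table(b=3000)           # 1 b0 + 81 directions
sampling = F.icosphere(3, hemisphere=True)        # 321 directions
operator = F.assemble_operator(F.build_response(gtab, sampling),
                               F.build_dictionary(sampling))

spec = F.PhantomSpec(crossing_directions(70.0), [0.25, 0.25], iso_fraction=0.5)
vol, truth = F.make_patch(spec, gtab, snr=20.0, n_voxels=121, seed=7)

cf = F.fit_field(vol, gtab, operator, F.SolverConfig())
render = F.icosphere(5)                           # 10 242 vertices
peaks = F.extract_peaks_field(cf, operator.basis, render)
report = F.evaluate_region(peaks, truth, crossing_angle=70.0)

print(f"mean AAE          : {report.aae:.2f} deg")
print(f"extra peaks (r+)  : {report.r_plus:.1f} %")
print(f"missed peaks (r-) : {report.r_minus:.1f} %")
print(f"mean P_iso        : {np.nanmean(F.p_iso_map(cf)):.3f}")
```

prints

```
mean AAE          : 3.57 deg
extra peaks (r+)  : 27.3 %
missed peaks (r-) : 0.0 %
mean P_iso        : 0.652
```

Both true fiber directions are recovered in every voxel to ~3.6° despite
half the signal being isotropic; about a quarter of the voxels carry one
extra small peak; P_iso sits above the true 0.5 because the simulated fiber
tensor (λ = (1.7, 0.2, 0.2) × 10⁻³ mm²/s) itself carries a perpendicular
attenuation floor that reads as partly isotropic against the FA = 1
response.

## Command line

```bash
irl simulate --mode voxel --angle 70 --iso 0.5 --snr 20 --seed 3 --out-dir phantom/
irl fit --dwi phantom/dwi.nii.gz --bvals phantom/dwi.bvals --bvecs phantom/dwi.bvecs \
        --out-dir fit/                      # coefficients, piso, gfa, peaks (NIfTI)
irl evaluate --coeffs fit/coefficients.nii.gz --truth phantom/truth.json --out report.csv
irl maps --coeffs fit/coefficients.nii.gz --out-dir maps/
```

`irl fit --calibrate` estimates the response pair from the data itself
(50 highest-/lowest-FA voxels) instead of the analytic FA = 1 / FA = 0 pair.

## Acceptance script

`scripts/acceptance.py` regenerates the hardest simulated condition from
scratch — a 121-voxel patch of two fibers crossing at 50° with only 10%
anisotropic volume fraction, 81 directions at b = 3000, Rician noise at
SNR 20 — fits it with the default settings, and writes the mean angular
error of the matched fODF peaks (degrees) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
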