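# Methods

## Signal model

A voxel's attenuation signal (S/S0, including the b = 0 entries at value 1)
is modeled as the sum of an orientation-resolved fiber compartment and a
free isotropic compartment:

```
S(g_i) = Σ_j R_ani(i, j) f_ani(v_j) + R_iso(i) f_iso .
```

`R_ani(i, j) = exp(−b_i λ∥ (g_i·v_j)²)` with λ∥ = 3·MD and MD =
0.7 × 10⁻³ mm²/s is the unique axially symmetric tensor response with
FA = 1 at that mean diffusivity (eigenvalues (3MD, 0, 0): fixing MD and
demanding maximal anisotropy forces the two transverse eigenvalues to
zero). `R_iso = exp(−b·MD)` is the FA = 0 response. The sampling
directions `v_j` are the 321 vertices of a three-fold subdivided
icosahedron restricted to a hemisphere (antipodal representative chosen by
nonnegative z, then y, then x, so indices are reproducible).

**The b = 0 rows are part of the operator.** An isotropic compartment and a
uniform angular spread of FA = 1 sticks with the same MD both produce a
direction-independent diffusion-weighted signal, but at different levels per
unit volume (exp(−b·MD) = 0.122 versus the powder average 0.353 at
b = 3000). On the DW rows alone the two are therefore exactly degenerate up
to a volume rescaling, and a fit is free to express isotropy through
dispersed sticks. The unit-attenuation b = 0 rows pin the total compartment
volume and break this degeneracy; dropping them makes P_iso recovery
impossible (a pure isotropic voxel fits with P_iso ≈ 0.003). This is the
same mechanism by which multi-tissue CSD separates compartments from
single-shell + b = 0 data.

## Dictionary

The fODF is expanded in L = J = 321 antipodally symmetric double-lobe atoms
`d(v, u_l) = κ₁ |cos ϑ_{v,u_l}|^τ`, peak-normalized (κ₁ = 1 so that
`d(u_l, u_l) = 1`). The augmented block matrix is

```
Φ = [[φ, 0],
     [0, μ]],        μ = mean_l Σ_j φ(j, l) ≈ 18.9 ,
```

so the isotropic coefficient feeds only the isotropic fODF entry. The
scale μ puts one unit of isotropic coefficient on the same *fODF-mass*
footing as one unit of anisotropic coefficient: with it, the coefficient
vector of a mixed voxel sums to (approximately) the voxel volume and
`P_iso = c_iso / Σc` reads directly as the isotropic volume fraction. With
an unscaled isotropic entry the two channels differ by a factor ≈ μ and the
index is uninterpretable.

**Kernel sharpness τ = 256 (default).** τ controls the trade-off between
fODF smoothness and two resolutions that the method must deliver:

* *angular resolution*: two lobes Δ apart merge into a single maximum when
  `2 cos^τ(Δ/2) > 1 + cos^τ(Δ)`; resolving a 40° crossing requires
  τ ≳ 12;
* *compartment resolution*: the kernel-blurred stick signal exceeds the
  true stick signal by a DC-like excess that the fit absorbs from the
  isotropic channel. The single-fiber representation error is 18% RMS at
  τ = 16, 6% at τ = 64, and 3% at τ = 128; isotropic-fraction recovery
  within ±0.1 needs τ ≳ 128.

τ = 256 (kernel FWHM ≈ 4°, weight 0.08 at the 8° atom spacing) satisfies
both with margin while still coupling neighboring atoms. Both the exponent
and the kernel family remain configurable; the literal printed fraction
kernel (`eq5_fraction`, a sin-based disc shape peaking perpendicular to the
atom) is available for comparison but is unsuitable for peak extraction.

## Solver

The data term is the Gaussian-likelihood multiplicative fixed point (ISRA)

```
c ← c ⊙ (AᵀS) ⊘ (AᵀA c),      A = R̂Φ,
```

which preserves nonnegativity and monotonically decreases ‖S − Ac‖². The
noise variance σ² cancels in the ratio and is dropped. Initialization is
uniform, `c⁰ = α·1` with α per voxel matching mean(Ac⁰) = mean(S); the
paper-style fixed budget of 200 iterations is the default stopping rule
(semi-convergence guard), with an optional relative-change early exit.

Two per-voxel multiplicative factors implement the regularization each
iteration, evaluated at the current iterate:

* **TV**, per coefficient channel across the voxel grid:
  `1/(1 − λ_TV div(∇c/|∇c|_ε))` with forward differences, exact negative-
  adjoint divergence, and Neumann boundaries. |∇c| is smoothed as
  `sqrt(|∇c|² + ε·s)` with `s` the channel's mean squared gradient, making
  ε = 10⁻⁸ dimensionless. The curvature term is unbounded at noise extrema,
  so the factor is capped at `tv_factor_max = 2` (denominator clamped at
  1/2); without the cap the multiplier reaches ~10¹² at λ_TV = 0.5 and the
  iteration diverges. Singleton spatial axes are skipped.
* **ℓ1 shrinkage** on the nonnegative orthant: `1/(1 + λ_ℓ1)` wherever
  c > 0. (The anti-shrinkage sign variant is retained behind
  `l1_mode="printed"` for comparison only.)

Defaults λ_TV = 0.5, λ_ℓ1 = 0.01. On the 11×11 partial-volume grid at
SNR 10 these cut the mean angular error roughly in half relative to the
unregularized fit; TV carries most of the noise robustness.

**Convergence caveat.** Plain ISRA contracts the redundant neighbor-atom
coefficients at a geometric rate of only ≈ 0.98 per iteration, so after 200
iterations the residual norm sits a few percent above the NNLS optimum, and
the slow isotropic mode (identifiable only through the b = 0 rows) reaches
its converged value after ~1000–2000 iterations. Noise-free validation of
P_iso therefore runs the scheme to convergence; the 200-iteration default
is kept for noisy data, where semi-convergence makes longer runs harmful.

## Phantoms

The simulator reproduces the standard two-compartment multi-tensor world:
fibers are axially symmetric Gaussian tensors with eigenvalues
(1.7, 0.2, 0.2) × 10⁻³ mm²/s (MD exactly 0.7 × 10⁻³, the conventional
two-tensor phantom profile at the stated MD), mixed with
`iso_fraction · exp(−b·MD)`, sampled on a packaged 81-direction hemisphere
scheme (electrostatic-repulsion minimization from a fixed seed, minimum
pairwise line angle 13.1°) plus one b = 0 volume. Rician noise takes the
magnitude of the complex-Gaussian-corrupted mixed signal with σ = S0/SNR.
"100 repetitions" are realized as homogeneous square patches (121 voxels,
one noise draw per voxel) so the spatial regularizers act as they would on
an image. The 11×11 grid sweeps iso fraction along x (11 evenly spaced
values from 0.1 to 1.0 — the stated endpoints; a strict 0.1 step would
give only 10 columns) against SNR 10..30 step 2 along y.

What the phantoms do *not* emulate: spatially varying fiber curvature,
non-Gaussian compartments (restriction, exchange), multi-shell acquisition,
eddy/motion artifacts, and tensor profiles differing from voxel to voxel. A
green phantom test therefore establishes model-consistency and noise
robustness, not in-vivo fidelity. In particular, because the simulated
fiber tensor has λ⊥ > 0 while the response assumes FA = 1, its perpendicular
attenuation floor exp(−b λ⊥) is genuinely part-isotropic: P_iso on these
phantoms is biased above the nominal mixing fraction, and exact fraction
recovery is validated with FA = 1 (response-matched) simulation tensors.

## Peak extraction and evaluation

fODFs are rendered by evaluating the atom kernels on a 10 242-vertex
full-sphere tessellation. Peaks are strict local maxima over mesh adjacency
with amplitude ≥ 0.1 of the per-voxel anisotropic maximum, greedily
suppressed within 25° (larger peak wins; antipodal duplicates collapse).
A peak is correct when it lies within min(crossing_angle/2, 35°) of an
unclaimed true direction (greedy assignment by ascending angle). AAE is the
per-voxel mean matched-pair angle averaged over voxels with at least one
match; r⁺/r⁻ are the per-voxel extra/missed counts averaged over the region
in percent. Scalar indices: FA = sqrt(3/2)·‖λ − λ̄‖/‖λ‖, GFA = std/rms
(n−1 in the variance, so a one-hot fODF gives exactly 1), GRA = population
std over mean (scale-invariant, 0 for constant fODFs).

## Response calibration from data

For real data the FA = 1 / FA = 0 pair can be replaced by a calibrated
pair: a linear least-squares tensor fit on log-attenuations per masked
voxel; the 50 highest-FA voxels are axially symmetrized (λ∥ = λ₁,
λ⊥ = (λ₂+λ₃)/2) and averaged to give the anisotropic profile re-oriented
to every sampling direction; the mean diffusivity of the 50 lowest-FA
voxels gives the isotropic profile. Calibration is parametric (averaged
tensor profiles rather than interpolated raw signals): on noise-free
phantom data it reproduces the analytic response to machine precision, and
on noisy data it avoids committing to a spherical interpolation scheme.

## Numerical choices

* Data-ratio denominators clamped at 10⁻¹²; coefficients below 10⁻¹² after
  the final iteration truncated to zero for sparsity reporting.
* Voxels with S0 ≤ 0 or zero signal are excluded from the mask.
* b0 detection threshold 50 s/mm² (FSL convention); gradients interpreted
  in the image frame (bvecs convention, no affine rotation).
* Hemisphere representative rule and the packaged 81-direction text asset
  make every tessellation and scheme bit-reproducible across platforms.

## Known limitations

* Single isotropic compartment (no separate GM/CSF diffusivities).
* The ℓ1 factor's printed sign and the exact published kernel parameters
  are ambiguous in the source material; the package's choices are recorded
  above and exposed in configuration.
* ISRA's slow tail (see Convergence caveat) means 200-iteration results
  are mildly under-converged by design.
* The in-vivo pipeline (CLI on arbitrary NIfTI) is functional but validated
  only on simulated data.
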