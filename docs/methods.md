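# Methods

## Distortion model

Off-resonance ΔB₀ (Hz) displaces signal along the phase-encoding (PE) axis
by `VSM = s_y·ΔB₀/(BW_PE·R)` mm, with `BW_PE = 1/(echo spacing × n_y)`.
The model is strictly one-dimensional: each PE line is warped by the
monotone map `f(y) = y + p·VSM(y)/s_y` (voxel units, `p = ±1` the PE
polarity). Acquisition constants live in `EPIGeometry`; the default
emulates a 3 T protocol (2.5 mm isotropic, 0.57 ms nominal echo spacing,
78 echoes, R = 2, so `BW_PE ≈ 22.5 Hz` and 1 Hz ≈ 0.056 mm).

**Forward warp and unwarping.** `apply_distortion` treats each voxel as a
box of uniform signal density and pushes it through `f`; the output voxel
collects the density falling into its pre-image interval (edges of the
interval found by inverting `f` per line with linear interpolation). This
flux form is the integral version of Jacobian intensity modulation —
compression brightens, stretching dims — and conserves the per-line
integral to machine precision, which is the physically correct behaviour
of a shifted, not lost, signal. `unwarp` is the corresponding pull with
the same flux construction. With `conserve_mass=False` both operators
point-sample with linear interpolation instead (no modulation), since it
is genuinely unknown whether production unwarpers modulate intensities;
both behaviours are exposed. Out-of-grid signal reads as zero.

**Invertibility.** A warp is accepted only if every edge interval has
positive width above a Jacobian floor of 0.05 voxel; violations raise
`NonInvertibleWarpError` with the offending line/edge index. The
practical precondition is |∂(VSM/s_y)/∂y| < 1.

**Resampling plans.** Because one shift map serves a whole 4-D run, the
per-line resampling weights are precomputed once (`PEResamplePlan`) and
applied to any volume or series as a batched matrix product.

## Synthetic data generator

`phantom_forge` emulates the study's inputs on a 48×64×32 grid at 2.5 mm
(PE along the second axis; runtimes in seconds):

- **head phantom** — nested ellipsoids: CSF rim, GM shell, WM core, two
  CSF ventricles; T1-like structural contrast (WM 1.0 > GM 0.65 > CSF
  0.25) and an EPI-like contrast (GM 1.0 > WM 0.72 > CSF 0.45); Gaussian
  tissue noise of 1% of WM intensity. WM boundary points with outward unit
  normals are extracted from the label map for the registration metric.
- **field** — low-order polynomial background (±17 Hz) plus Gaussian
  offsets: +250 Hz (σ = 12 mm) at an anterior-inferior "sinus" location
  and −140 Hz (σ = 10 mm) temporally, spanning roughly −140…+245 Hz inside
  the brain — the scale reported near air cavities at 3 T — while keeping
  the warp invertible (peak shift slope ≈ 0.69 voxel/voxel).
- **dual-echo GRE** — complex echoes `M·e^{-TE/T2*}·e^{i2πΔB₀TE}` at
  TE 4.92/7.38 ms (ΔTE 2.46 ms) with complex Gaussian noise, so
  magnitudes are Rician and the wrapped phase difference (−π, π] carries
  1/SNR phase noise. GRE images are geometrically undistorted.
- **EPI runs** — BOLD series `baseline·(1 + task + networks)`; the task is
  a boxcar (default five 14 s blocks) convolved with the canonical
  double-gamma HRF, scaled to 2% signal change inside a spherical active
  region placed in the high-|ΔB₀| zone; three spherical "network" masks
  fluctuate with independent low-frequency (< 0.1 Hz) time courses at 1%.
  Every volume is warped with the true shift map (AP, polarity +1); ten
  task-free calibration volumes are warped with polarity −1 (PA); Gaussian
  noise (default 2% of mean brain intensity) is added in the distorted
  frame. All generators are deterministic under a seed.

What the phantom does **not** model: through-plane dephasing/dropout,
head motion and its interaction with the field, physiological noise,
temporal autocorrelation, k-space/GRAPPA reconstruction, and the
cross-modality registration needed on real data (all grids are aligned by
construction). Passing tests therefore demonstrate the correctness of the
estimators and metrics under the stated physics, not robustness to those
real-data effects.

## Field-map (GRE) chain

`rescale_phase` maps integer-coded exports onto (−π, π] treating the range
as one full cycle of `hi−lo+1` bins. `unwrap_phase` uses the
reliability-sorting unwrapper from scikit-image per connected mask
component (components are independent up to 2π, so multiples are
indeterminate across them — a warning says so), then re-anchors each
component so its seed voxel (highest magnitude in the full chain) keeps
its wrapped value; the output equals the input modulo 2π everywhere at
1e-9. Division by ΔTE and 2π gives ΔB₀ in Hz. `smooth_field` smooths
within the mask with mask-renormalised Gaussian weights (default FWHM
4 mm, the pipeline's spatial smoothing scale; 0 disables). Before
unwarping, the field is extended outside the mask by nearest-inside value
plus a relaxation smoothing of the outside region only — the raw phase has
no meaning without signal, and leaving wrapped noise there produces
non-invertible warps. The brain mask defaults to 0.75 × Otsu threshold of
the first-echo magnitude (largest component, holes filled).

On the noise-free phantom without smoothing the chain recovers the field
to < 1e-14 Hz; at GRE SNR 50 with 4 mm smoothing the shift map is
recovered to ≈ 0.1 mm RMSE.

## Reversed-PE (blip-up/blip-down) estimator

The shift map `v` (mm, AP convention) minimises

```
½ Σ_mask [U₊(AP; v) − U₋(PA; v)]² + ½ λ ‖L c‖²
```

where `U±` unwarp with ±v including Jacobian modulation, `v` is a
tensor-product cubic B-spline field with coefficients `c` (default knot
spacing 12 mm), and `L` is a discrete Laplacian on the coefficient grid (a
bending-energy surrogate). λ defaults to 0.01 × (data term at the level's
initial iterate)/(bending of an all-ones coefficient field): scaling to
the *initialised* residual makes the penalty track the noise floor rather
than the unaligned misfit, which would otherwise over-regularise by
orders of magnitude.

The optimisation is coarse-to-fine (Gaussian pre-smoothing 8/4/2 mm) with
two ingredients per iteration, both gated by a strict-decrease line search
so the accepted objective is monotonically non-increasing:

1. **projected midway correction** — with mass-conserving distortions the
   cumulative intensity along each PE line is invariant under the warp, so
   positions of equal cumulative mass in the two (residually distorted)
   images are images of one true position and the residual shift is half
   their separation. This closed-form estimate, projected onto the spline
   basis by weighted least squares (weak pull to zero outside the mask,
   bending-regularised), also provides the initialisation.
2. **Gauss–Newton step** — using the full linearisation of the modulated
   unwarp, `dr/dv = g₁ + g₂·∂/∂y`: `g₁` from central differences of the
   operator under a uniform shift, `g₂` the point-sampled pair intensity
   divided by `s_y` (the modulation derivative). The normal equations are
   solved by Jacobi-preconditioned conjugate gradients with mild Levenberg
   damping; infeasible (non-invertible) candidates score +∞ and the line
   search backs off. Omitting the `g₂` term stalls the fit at ≈ 0.2 mm
   RMSE; with it the estimator reaches ≈ 0.05 mm at 2% noise, and the
   corrected pair difference reaches the noise floor.

The AP reference is the middle volume of the run and the PA reference the
last calibration volume; the single estimated field corrects every volume
of the series. Swapping the inputs negates the estimate; identical inputs
give an (essentially) zero field.

## Assessment metrics

- **nMSE** `= 2Σ(A−B)²/Σ(A²+B²)` over the mask — symmetric, 0 iff equal,
  2 against a zero image. The symmetric denominator is this package's
  choice; absolute values depend on it.
- **cross-correlation** — Pearson over mask voxels (chosen over a raw
  normalised inner product; documented because the convention affects
  absolute values).
- **Dice** `= 2|A∩B|/(|A|+|B|)`; empty∩empty returns 0 with a warning.
- **network assignment** — components thresholded at Z > 3 are assigned to
  templates sequentially and mutually exclusively (greedy per ordering);
  all T! template orderings are enumerated when T! ≤ 10000, otherwise that
  many are sampled with a fixed seed; the ordering with the highest mean
  Dice wins. Component ties break to the lowest index.
- **BBR cost** — the image is sampled 2 mm inside and outside each WM
  boundary point along its normal; the percent contrast Q is soft-clipped
  through `(1 + tanh(slope·Q/100))/2` and averaged. Slope +0.5 expects
  bright-inside (T1-like) contrast; the pipeline scores EPI volumes with
  slope −0.5 because EPI has GM brighter than WM. A uniform image scores
  0.5; misregistration mixes tissues across the boundary and pushes the
  cost toward 0.5 from the well-aligned side.
- **per-ROI shift ranges** — min/max of the shift map over each network
  mask.

## Functional analyses

Preprocessing: discrete-cosine high-pass (all basis functions with period
above the 100 s cutoff, plus the mean) then Gaussian smoothing (4 mm
FWHM). GLM: voxel-wise OLS with the HRF-convolved boxcar and an intercept;
t → Z by the normal-quantile transform of the t tail probability, capped
at |Z| = 38 (beyond double precision of the tail); under white noise the
|Z| > 1.96 rate is 5%, the module's core calibration contract. Cluster
inference keeps 26-connected suprathreshold (Z > 2.5) components of at
least 10 voxels — a fixed extent threshold replacing random-field cluster
p-values, a documented simplification. Group maps average within subject
(fixed effects) and take a one-sample t across subjects; zero-variance
voxels are flagged. Spatial ICA concatenates runs in time,
variance-normalises voxels, and runs FastICA over the spatial dimension
with fixed order (pipeline default 6 on the desk-scale phantom, where
three networks are planted; the module accepts any K); maps are z-scored
and sign-fixed to non-negative skewness. Prewhitening is omitted: the
generator draws white noise, so OLS is exact.

## Pipeline and reproducibility

`RunConfig` (pydantic-validated, YAML-serialisable) fixes every parameter
of one experiment; `full_run` derives all RNG streams from the single seed
and produces the uncorrected, reversed-PE- and field-map-corrected
branches plus the full table set; reports serialise to CSV with a column
schema that is validated on reload. Identical seeds give byte-identical
reports. A default run (140 volumes) completes in a few minutes on one
CPU; the test suite uses shortened series for the end-to-end checks.

## Known limitations

- The estimators assume the 1-D distortion model exactly; real data add
  through-plane effects neither approach corrects.
- The field-map branch on this phantom is close to oracle-grade because
  the GRE images are perfectly aligned with the EPI grid; on real data its
  accuracy is limited by cross-modality registration, which is out of
  scope here.
- The reversed-PE spline resolution (12 mm knots) bounds how sharp a field
  gradient can be represented; fields varying faster than the knot spacing
  would need a finer grid at higher noise sensitivity.
- Cluster extent thresholding has no false-positive-rate calibration; it
  is a structural stand-in for random-field inference.
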