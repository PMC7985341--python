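# epiwarp

Simulation, correction and quantitative assessment of the geometric
distortions that B₀ field inhomogeneity induces in echo-planar (EPI) fMRI
data.

## The problem

Gradient-echo EPI accumulates off-resonance phase between phase-encoding
(PE) steps, so a voxel sitting in a local field offset ΔB₀ (Hz) appears
displaced along the PE axis by

```
VSM = s_y · ΔB₀ / (BW_PE · R),      BW_PE = 1 / (echo spacing × n_y)
```

where `s_y` is the PE voxel size (mm), `n_y` the number of echoes per
excitation, and `R` the in-plane acceleration factor. Near air-filled
sinuses the offsets reach hundreds of Hz, shifting and compressing tissue
by several voxels — enough to corrupt registration, network identification
and activation mapping.

Two standard corrections estimate the per-voxel shift map and invert it:

- **field mapping (GRE)** — a dual-echo gradient-echo scan gives a wrapped
  phase difference `2π·ΔB₀·ΔTE`; rescaling, unwrapping, dividing by ΔTE
  and smoothing yields ΔB₀ and hence the shift map;
- **reversed phase encoding (blip-up/blip-down)** — two EPI volumes with
  opposite PE polarity carry mirrored distortions; the undistorted image
  lies midway, and the shift map is the field that, applied with opposite
  signs, makes the two unwarped images agree.

`epiwarp` implements the distortion physics (mass-conserving 1-D warps with
Jacobian intensity modulation), both correction chains, a synthetic head
phantom with a ground-truth field, and every assessment statistic of a
distortion-correction study: shift-map ranges, PA/AP normalised MSE and
cross-correlation, boundary-based-registration cost, spatial-ICA network
identification with randomized mutually-exclusive Dice assignment, and
block-design GLM activation mapping.

## Worked example

```python
import numpy as np, warnings
from epiwarp import phantom, topup, metrics
from epiwarp.fieldmap import correct_gre
from epiwarp.warp import EPIGeometry, PEResamplePlan, db0_to_vsm

geom = EPIGeometry(voxel_size_pe=2.5, n_pe=78, echo_spacing_s=0.57e-3,
                   accel=2, pe_axis=1)
spec = phantom.PhantomSpec(seed=0)
structural, truth = phantom.make_phantom(spec)
field = phantom.make_field(spec)
vsm_true = db0_to_vsm(field, geom)
m = truth.brain_mask
print(f"field range inside brain: {field.values[m].min():.0f} to {field.values[m].max():.0f} Hz")
print(f"implied shift range:      {vsm_true.values[m].min():.1f} to {vsm_true.values[m].max():.1f} mm")

base = phantom.epi_baseline(truth.tissue_labels, spec)
run = phantom.synth_epi_run(truth, field, geom, phantom.TaskDesign(), spec,
                            noise_sd=0.02 * base[m].mean(), seed=0)
ap = np.asarray(run.ap[..., run.ap.shape[-1] // 2], float)   # middle AP volume
pa = np.asarray(run.pa[..., -1], float)                      # last PA volume
print(f"PA/AP nMSE uncorrected:   {metrics.nmse(pa, ap, m):.4f}")

pair = topup.ReversedPair(ap_volume=ap, pa_volume=pa, geom=geom)
result = topup.estimate_field_topup(pair)
ap_c, pa_c, _ = topup.correct_pair(pair, result.vsm)
rmse = np.sqrt(np.mean((result.vsm.values[m] - vsm_true.values[m]) ** 2))
print(f"PA/AP nMSE reversed-PE:   {metrics.nmse(pa_c, ap_c, m):.4f}  (shift-map RMSE {rmse:.2f} mm)")

dual = phantom.synth_dual_echo(structural, field,
                               noise_sd=structural[m].mean() / 50, seed=0)
_, f_est, v_est = correct_gre(ap, dual, geom, fwhm_mm=4.0)
ap_g = PEResamplePlan(v_est, geom.with_polarity(+1), "unwarp")(ap)
pa_g = PEResamplePlan(v_est, geom.with_polarity(-1), "unwarp")(pa)
rmse_g = np.sqrt(np.mean((v_est.values[m] - vsm_true.values[m]) ** 2))
print(f"PA/AP nMSE field-map:     {metrics.nmse(pa_g, ap_g, m):.4f}  (shift-map RMSE {rmse_g:.2f} mm)")
```

prints

```
field range inside brain: -138 to 245 Hz
implied shift range:      -7.7 to 13.6 mm
PA/AP nMSE uncorrected:   0.0683
PA/AP nMSE reversed-PE:   0.0009  (shift-map RMSE 0.05 mm)
PA/AP nMSE field-map:     0.0018  (shift-map RMSE 0.11 mm)
```

The two distorted acquisitions disagree badly before correction
(nMSE 0.068); both chains recover the hidden shift map to a tenth of a
millimetre and bring the pair into agreement, the reversed-PE estimate
slightly more so because it minimises exactly this difference — the same
qualitative ordering the assessment metrics are designed to expose.

The full pipeline — simulate, correct with both approaches, and emit the
complete table set (shift ranges, pair differences, between-method
consistency, BBR cost, network Dice, per-network shift ranges, activation
Z summaries) — is one call:

```python
from epiwarp import pipeline
report = pipeline.full_run(pipeline.RunConfig(seed=0))
pipeline.report_tables(report, "out/")
```

or, from a shell, `epiwarp full-run out/ --seed 0` (see also `epiwarp
simulate`, `epiwarp correct-gre`, `epiwarp correct-topup`, `epiwarp
assess`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its limits, the numerical choices, and the design decisions.
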