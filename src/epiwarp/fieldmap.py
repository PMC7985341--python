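"""Field-map (dual-echo GRE) distortion correction chain.

A dual-echo gradient-echo acquisition yields two magnitude images and one
phase-difference image.  The chain estimates the off-resonance field and
unwarps the EPI data:

1. rescale the stored phase difference onto ``(-pi, pi]``,
2. spatially unwrap it inside a brain mask,
3. divide by the echo-time difference to get rad/s, then by ``2*pi`` for Hz,
4. optionally smooth the field within the mask,
5. convert to a voxel-shift map and unwarp.

Step 2 delegates to scikit-image's reliability-sorting unwrapper, with the
result re-anchored so the seed voxel (highest magnitude by default) keeps
its wrapped value; the output differs from the input by exact multiples of
``2*pi`` everywhere.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase as _ski_unwrap

from .warp import (EPIGeometry, FieldOffsetMap, PEResamplePlan, VoxelShiftMap,
                   TWO_PI, db0_to_vsm, radps_to_hz)


@dataclass
class DualEchoGRE:
    """Dual-echo GRE data: two magnitudes and a wrapped phase difference."""

    magnitude1: np.ndarray
    magnitude2: np.ndarray
    phase_diff: np.ndarray  # radians in (-pi, pi]
    te1_s: float
    te2_s: float

    def __post_init__(self):
        if self.te2_s <= self.te1_s:
            raise ValueError("TE2 must be greater than TE1 (dTE > 0)")
        if self.magnitude1.shape != self.phase_diff.shape \
                or self.magnitude2.shape != self.phase_diff.shape:
            raise ValueError("magnitude and phase grids must share one shape")
        p = self.phase_diff
        if np.nanmin(p) < -np.pi - 1e-9 or np.nanmax(p) > np.pi + 1e-9:
            raise ValueError("phase_diff must lie in (-pi, pi] radians")

    @property
    def dte_s(self) -> float:
        return self.te2_s - self.te1_s


def rescale_phase(raw: np.ndarray, input_range: tuple | None = None) -> np.ndarray:
    """Affine map of a stored phase image onto ``(-pi, pi]``.

    ``input_range = (lo, hi)`` describes an integer-coded export with
    ``hi - lo + 1`` quantisation bins covering one full cycle, so ``hi``
    maps to exactly ``+pi`` and ``lo`` to ``-pi`` plus one quantum (the
    interval is half-open).  With ``input_range=None`` the input is assumed
    to already be in radians and is returned unchanged after validation.
    """
    raw = np.asarray(raw, dtype=float)
    if input_range is None:
        if raw.size and (raw.min() <= -np.pi - 1e-9 or raw.max() > np.pi + 1e-9):
            raise ValueError("input claims to be radians but falls outside (-pi, pi]")
        return raw.copy()
    lo, hi = float(input_range[0]), float(input_range[1])
    if hi <= lo:
        raise ValueError("zero-width input range")
    quantum = TWO_PI / (hi - lo + 1.0)
    return (raw - lo + 1.0) * quantum - np.pi


def unwrap_phase(wrapped: np.ndarray, mask: np.ndarray | None = None,
                 anchor: tuple | None = None) -> np.ndarray:
    """Spatially unwrap a wrapped phase image inside a mask.

    Every output voxel differs from the input by an integer multiple of
    ``2*pi``.  The solution in each connected mask component is anchored so
    the anchor voxel (or, absent one, the component voxel nearest its
    centroid) keeps its wrapped value.  Disconnected components are
    unwrapped independently with a warning, since the ``2*pi`` offsets
    between them are indeterminate.  Voxels outside the mask pass through
    unchanged.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if mask is None:
        mask = np.ones(wrapped.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    out = wrapped.copy()
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} disconnected components; phase offsets between "
            "them are indeterminate", stacklevel=2)
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        ma = np.ma.MaskedArray(wrapped, mask=~comp_mask)
        unw = np.asarray(_ski_unwrap(ma, wrap_around=False))
        if anchor is not None and comp_mask[tuple(anchor)]:
            seed = tuple(anchor)
        else:
            idx = np.argwhere(comp_mask)
            centroid = idx.mean(axis=0)
            seed = tuple(idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))])
        offset = TWO_PI * np.round((unw[seed] - wrapped[seed]) / TWO_PI)
        out[comp_mask] = unw[comp_mask] - offset
    return out


def phase_to_field(unwrapped: np.ndarray, dte_s: float) -> np.ndarray:
    """Convert an unwrapped phase difference (rad) to rad/s via ``phi / dTE``."""
    if dte_s <= 0:
        raise ValueError("dTE must be > 0")
    return np.asarray(unwrapped, dtype=float) / dte_s


def smooth_field(field: FieldOffsetMap, fwhm_mm: float,
                 voxel_size) -> FieldOffsetMap:
    """Gaussian smoothing inside the brain mask with mask-renormalised weights.

    ``fwhm_mm = 0`` is the identity.  Renormalisation (dividing the smoothed
    masked field by the smoothed mask) keeps constant fields exactly
    constant and avoids pulling the field toward zero at the mask edge.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return FieldOffsetMap(field.values.copy(), field.brain_mask)
    sigma_vox = [fwhm_mm / 2.35482 / v for v in np.broadcast_to(voxel_size, (field.values.ndim,))]
    m = field.brain_mask.astype(float)
    num = ndimage.gaussian_filter(field.values * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = field.values.copy()
    inside = field.brain_mask
    out[inside] = num[inside] / np.maximum(den[inside], 1e-12)
    return FieldOffsetMap(out, field.brain_mask)


def extend_field_outside_mask(field: FieldOffsetMap) -> FieldOffsetMap:
    """Replace outside-mask voxels with the nearest inside-mask field value.

    Phase (and hence field) estimates are meaningless where there is no
    signal; nearest-neighbour extension keeps the implied warp smooth and
    invertible across the mask edge instead of jumping to wrapped noise.
    """
    mask = field.brain_mask
    if mask.all():
        return field
    idx = ndimage.distance_transform_edt(~mask, return_distances=False,
                                         return_indices=True)
    extended = field.values[tuple(idx)]
    # the nearest-neighbour fill is piecewise constant and can jump between
    # adjacent lines where the closest surface point changes; relax the
    # outside region (only) toward a smooth continuation
    relaxed = extended.copy()
    for _ in range(3):
        relaxed = ndimage.gaussian_filter(relaxed, 2.0)
        relaxed[mask] = extended[mask]
    out = extended.copy()
    out[~mask] = relaxed[~mask]
    return FieldOffsetMap(out, mask)


def brain_mask_from_magnitude(magnitude: np.ndarray,
                              otsu_fraction: float = 0.75) -> np.ndarray:
    """Threshold mask from a magnitude image at a fraction of the Otsu level.

    Keeps the largest connected component and fills holes.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    thr = otsu_fraction * threshold_otsu(magnitude)
    mask = magnitude > thr
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def correct_gre(epi, dual_echo: DualEchoGRE, geom: EPIGeometry,
                fwhm_mm: float = 4.0, mask: np.ndarray | None = None,
                conserve_mass: bool = True):
    """Full GRE chain: phase -> field -> shift map -> unwarped EPI.

    ``epi`` may be a 3-D volume or a 4-D series (time last); the estimated
    field (Hz) and shift map (mm) are returned alongside the corrected data
    so the assessment stage can compare them against ground truth.
    """
    if mask is None:
        mask = brain_mask_from_magnitude(dual_echo.magnitude1)
    anchor = np.unravel_index(
        np.argmax(np.where(mask, dual_echo.magnitude1, -np.inf)), mask.shape)
    unwrapped = unwrap_phase(dual_echo.phase_diff, mask, anchor=anchor)
    radps = phase_to_field(unwrapped, dual_echo.dte_s)
    field = radps_to_hz(radps, mask)
    field = smooth_field(field, fwhm_mm, _infer_voxel_size(geom, field.values.ndim))
    field = extend_field_outside_mask(field)
    vsm = db0_to_vsm(field, geom)
    plan = PEResamplePlan(vsm, geom, "unwarp", conserve_mass=conserve_mass)
    corrected = plan(np.asarray(epi, dtype=float))
    return corrected, field, vsm


def _infer_voxel_size(geom: EPIGeometry, ndim: int):
    # maps are isotropic at the PE voxel size in this pipeline; keep the
    # helper separate so anisotropic grids can override it
    return [geom.voxel_size_pe] * ndim
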