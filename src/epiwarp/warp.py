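"""Distortion physics along the phase-encoding (PE) axis.

Off-resonance (a local deviation :math:`\\Delta B_0` from the nominal static
field, in Hz) accumulates between EPI phase-encoding steps and displaces
signal along the PE axis.  The displacement in mm is

.. math:: \\mathrm{VSM} = s_y \\cdot \\Delta B_0 / (BW_{PE} \\cdot R)

with :math:`s_y` the PE voxel size, :math:`BW_{PE} = 1/(\\mathrm{echo\\
spacing} \\times n_y)` the bandwidth per voxel in the PE direction, and
:math:`R` the in-plane acceleration factor.  This module holds the
acquisition geometry, the field/shift containers, and the 1-D forward
(distorting) and inverse (unwarping) resampling operators.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

#: Lower clamp on the 1-D warp Jacobian (voxel units).  Lines whose forward
#: map compresses more strongly than this are rejected as non-invertible.
JACOBIAN_FLOOR = 0.05


class NonInvertibleWarpError(ValueError):
    """Raised when a shift map violates the 1-D monotonicity condition."""

    def __init__(self, n_bad: int, example_index: tuple):
        self.n_bad = n_bad
        self.example_index = example_index
        super().__init__(
            f"warp is not invertible: {n_bad} PE-line edge(s) have a forward-map "
            f"slope below {JACOBIAN_FLOOR} (first at line/edge index {example_index}); "
            "the shift map changes faster than one voxel per voxel along PE"
        )


@dataclass(frozen=True)
class EPIGeometry:
    """Acquisition constants that turn a field offset into a voxel shift.

    Parameters
    ----------
    voxel_size_pe:
        Voxel size along the phase-encoding axis, mm.
    n_pe:
        Number of echoes per excitation along PE (matrix lines actually
        traversed, before acceleration).
    echo_spacing_s:
        Nominal echo spacing in seconds.  The acceleration factor divides
        it; using the effective spacing with ``accel=1`` is equivalent.
    accel:
        In-plane (GRAPPA-style) acceleration factor R, >= 1.
    pe_axis:
        Index of the PE axis in the voxel grid.
    pe_polarity:
        +1 for anterior->posterior encoded acquisitions, -1 for reversed
        (posterior->anterior) acquisitions.
    """

    voxel_size_pe: float
    n_pe: int
    echo_spacing_s: float
    accel: int = 1
    pe_axis: int = 1
    pe_polarity: int = 1

    def __post_init__(self):
        if not self.voxel_size_pe > 0:
            raise ValueError("voxel_size_pe must be > 0")
        if int(self.n_pe) < 2:
            raise ValueError("n_pe must be an integer >= 2")
        if not self.echo_spacing_s > 0:
            raise ValueError("echo_spacing_s must be > 0")
        if int(self.accel) < 1:
            raise ValueError("accel must be an integer >= 1")
        if self.pe_polarity not in (1, -1):
            raise ValueError("pe_polarity must be +1 or -1")
        if self.pe_axis < 0:
            raise ValueError("pe_axis must be a non-negative axis index")

    @property
    def bw_pe(self) -> float:
        """Bandwidth per voxel in the PE direction, Hz."""
        return 1.0 / (self.echo_spacing_s * self.n_pe)

    def with_polarity(self, polarity: int) -> "EPIGeometry":
        return dataclasses.replace(self, pe_polarity=polarity)


def _validated_map(values: np.ndarray, brain_mask, kind: str):
    values = np.asarray(values, dtype=float)
    if brain_mask is None:
        brain_mask = np.ones(values.shape, dtype=bool)
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != values.shape:
        raise ValueError(f"{kind}: mask shape {brain_mask.shape} != values shape {values.shape}")
    if not np.all(np.isfinite(values[brain_mask])):
        raise ValueError(f"{kind}: non-finite values inside the brain mask")
    return values, brain_mask


@dataclass
class FieldOffsetMap:
    """Per-voxel static-field deviation :math:`\\Delta B_0` in Hz."""

    values: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values, self.brain_mask = _validated_map(self.values, self.brain_mask, "FieldOffsetMap")


@dataclass
class VoxelShiftMap:
    """Per-voxel displacement along PE, in mm.

    Sign convention: on an AP-encoded image (``pe_polarity=+1``) a positive
    shift moves signal toward larger PE index; negative values correspond to
    shifts in the anterior-to-posterior direction.
    """

    values: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values, self.brain_mask = _validated_map(self.values, self.brain_mask, "VoxelShiftMap")


def radps_to_hz(field, brain_mask=None) -> FieldOffsetMap:
    """Convert a per-voxel angular-frequency offset (rad/s) to Hz.

    The conversion divides by ``2*pi``.  Accepts a bare array or a
    :class:`FieldOffsetMap` carrying rad/s values.
    """
    if isinstance(field, FieldOffsetMap):
        brain_mask = field.brain_mask if brain_mask is None else brain_mask
        field = field.values
    values = np.asarray(field, dtype=float)
    out = FieldOffsetMap(values / TWO_PI, brain_mask)
    return out


def db0_to_vsm(field: FieldOffsetMap, geom: EPIGeometry) -> VoxelShiftMap:
    """Map a field-offset map (Hz) to a voxel shift map (mm).

    Linear in the field:  ``vsm_mm = s_y * dB0 / (BW_PE * R)``.
    """
    if not isinstance(field, FieldOffsetMap):
        field = FieldOffsetMap(field)
    vsm = geom.voxel_size_pe * field.values / (geom.bw_pe * geom.accel)
    return VoxelShiftMap(vsm, field.brain_mask)


# ---------------------------------------------------------------------------
# 1-D resampling along PE
# ---------------------------------------------------------------------------

def _as_lines(vol: np.ndarray, pe_axis: int) -> np.ndarray:
    """View of ``vol`` as (n_lines, n_pe) with PE last."""
    v = np.moveaxis(np.asarray(vol, dtype=float), pe_axis, -1)
    return np.ascontiguousarray(v.reshape(-1, v.shape[-1])), v.shape


def _from_lines(lines: np.ndarray, moved_shape: tuple, pe_axis: int) -> np.ndarray:
    return np.moveaxis(lines.reshape(moved_shape), -1, pe_axis)


class PEResamplePlan:
    """Precomputed per-line resampling operator for a 1-D warp along PE.

    The forward (distorting) map sends true position ``y`` to
    ``y + pe_polarity * vsm(y) / s_y`` (voxel units).  ``mode="apply"``
    realises that push; ``mode="unwarp"`` realises the inverse pull.  With
    ``conserve_mass`` the operator is flux-conserving: each voxel is treated
    as a box of uniform signal density and the output voxel collects the
    signal falling into its (mapped-back) interval, which preserves the
    integral along every PE line exactly and is equivalent to Jacobian
    intensity modulation.  Without it the operator point-samples with linear
    interpolation and zero background.

    Because the shift map is shared by all volumes of a run, the plan is
    built once (it stores one small resampling matrix per PE line) and can
    then be applied to any 3-D volume or 4-D series on the same grid.
    """

    def __init__(self, vsm, geom: EPIGeometry, mode: str, conserve_mass: bool = True):
        if mode not in ("apply", "unwarp"):
            raise ValueError("mode must be 'apply' or 'unwarp'")
        values = vsm.values if isinstance(vsm, VoxelShiftMap) else np.asarray(vsm, dtype=float)
        self.grid_shape = values.shape
        self.pe_axis = geom.pe_axis
        shift_vox = geom.pe_polarity * values / geom.voxel_size_pe
        s_lines, self._moved_shape = _as_lines(shift_vox, geom.pe_axis)
        n_lines, n = s_lines.shape

        # Forward map evaluated at voxel edges (half-integer grid).
        yh = np.arange(n + 1) - 0.5
        sh = np.empty((n_lines, n + 1))
        sh[:, 1:-1] = 0.5 * (s_lines[:, :-1] + s_lines[:, 1:])
        sh[:, 0] = s_lines[:, 0]
        sh[:, -1] = s_lines[:, -1]
        fwd = yh[None, :] + sh
        dfwd = np.diff(fwd, axis=1)
        bad = dfwd <= JACOBIAN_FLOOR
        if bad.any():
            idx = np.argwhere(bad)
            raise NonInvertibleWarpError(int(bad.sum()), tuple(idx[0]))

        j = np.arange(n)
        if mode == "unwarp":
            edges = fwd
            centers = np.arange(n)[None, :] + s_lines
            valid = np.ones_like(centers, dtype=bool)
        else:
            edges = np.empty_like(fwd)
            for li in range(n_lines):
                edges[li] = np.interp(yh, fwd[li], yh)
            f_int = np.arange(n)[None, :] + s_lines
            centers = np.empty_like(f_int)
            for li in range(n_lines):
                centers[li] = np.interp(j, f_int[li], j)
            valid = (j >= f_int[:, :1]) & (j <= f_int[:, -1:])

        if conserve_mass:
            cum = np.clip(edges[:, :, None] - (j[None, None, :] - 0.5), 0.0, 1.0)
            weights = np.diff(cum, axis=1)
        else:
            pos = np.where(valid, centers, -10.0)
            weights = np.clip(1.0 - np.abs(pos[:, :, None] - j[None, None, :]), 0.0, 1.0)
        self._weights = weights

    def __call__(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data)
        nd = len(self.grid_shape)
        if data.ndim == nd:
            if data.shape != self.grid_shape:
                raise ValueError(f"volume shape {data.shape} != plan grid {self.grid_shape}")
            lines, moved = _as_lines(data, self.pe_axis)
            out = np.einsum("lkj,lj->lk", self._weights, lines)
            return _from_lines(out, moved, self.pe_axis)
        if data.ndim == nd + 1:
            if data.shape[:nd] != self.grid_shape:
                raise ValueError(f"series spatial shape {data.shape[:nd]} != plan grid {self.grid_shape}")
            # time on the last axis
            v = np.moveaxis(np.asarray(data, dtype=float), self.pe_axis, -2)
            lead = v.shape
            lines = v.reshape(-1, v.shape[-2], v.shape[-1])
            out = np.einsum("lkj,ljt->lkt", self._weights, lines)
            return np.moveaxis(out.reshape(lead), -2, self.pe_axis)
        raise ValueError("data must be a volume on the plan grid or a series with time last")


def apply_distortion(volume: np.ndarray, vsm, geom: EPIGeometry,
                     conserve_mass: bool = True) -> np.ndarray:
    """Forward-distort a volume: push each voxel along PE by its shift.

    Signal originating at voxel ``y`` appears at ``y + pe_polarity*vsm/s_y``;
    with ``conserve_mass`` intensities are modulated by the warp Jacobian so
    compression brightens and stretching dims, preserving the per-line
    integral.  Out-of-grid signal is lost to a zero background.
    """
    return PEResamplePlan(vsm, geom, "apply", conserve_mass)(volume)


def unwarp(volume: np.ndarray, vsm, geom: EPIGeometry,
           conserve_mass: bool = True) -> np.ndarray:
    """Invert :func:`apply_distortion` given the (estimated) shift map."""
    return PEResamplePlan(vsm, geom, "unwarp", conserve_mass)(volume)
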