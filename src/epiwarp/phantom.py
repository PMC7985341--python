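"""Synthetic head phantom, off-resonance field and distorted EPI data.

The generator emulates the inputs of a susceptibility-distortion study: a
multi-tissue head phantom (WM / GM / CSF with ventricles), a smooth
:math:`\\Delta B_0` field with focal offsets near air-filled "sinus"
regions, dual-echo gradient-echo (GRE) magnitude + wrapped phase-difference
images, and 4-D EPI runs distorted with opposite signs for the AP and PA
phase-encoding polarities, carrying block-design BOLD activation and
low-frequency network fluctuations.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fieldmap import DualEchoGRE
from .fmri import double_gamma_hrf
from .warp import (EPIGeometry, FieldOffsetMap, PEResamplePlan, VoxelShiftMap,
                   db0_to_vsm)

LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3}

# Tissue means on a T1-like structural contrast (WM bright) and an EPI-like
# (T2*-weighted) contrast where GM is brightest and WM darker -- the sign of
# the WM/GM boundary contrast matters for the boundary-registration metric.
_STRUCT_MEANS = {"background": 0.0, "csf": 0.25, "gm": 0.65, "wm": 1.0}
_EPI_MEANS = {"background": 0.0, "csf": 0.45, "gm": 1.0, "wm": 0.72}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of the synthetic head.

    Defaults give a 48 x 64 x 32 grid at 2.5 mm isotropic (PE along the
    second axis), a field spanning roughly -140 to +260 Hz inside the brain
    (the scale seen near frontal/temporal air cavities at 3 T), and tissue
    noise of 1% of the WM intensity.  Blob amplitudes and widths are chosen
    so the implied voxel-shift map keeps the 1-D warp invertible.
    """

    grid_shape: tuple = (48, 64, 32)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    tissue_means: dict = dc_field(default_factory=lambda: dict(_STRUCT_MEANS))
    tissue_noise_sd: dict = dc_field(default_factory=lambda: {
        "background": 0.0, "csf": 0.01, "gm": 0.01, "wm": 0.01})
    epi_tissue_means: dict = dc_field(default_factory=lambda: dict(_EPI_MEANS))
    brain_radius_frac: float = 0.40
    wm_radius_frac: float = 0.72
    csf_rim_frac: float = 0.93
    #: ventricles: (fractional center, radii in mm)
    ventricles: tuple = (
        ((0.42, 0.52, 0.55), (5.0, 14.0, 6.0)),
        ((0.58, 0.52, 0.55), (5.0, 14.0, 6.0)),
    )
    #: focal field offsets: (fractional center, width mm, amplitude Hz).
    #: The positive blob sits anterior-inferior ("sinus" region), the
    #: negative one temporal.
    sinus_blobs: tuple = (
        ((0.50, 0.82, 0.30), 12.0, 250.0),
        ((0.22, 0.55, 0.35), 10.0, -140.0),
    )
    #: low-order background field: (c0, cx, cy, cz) in Hz on [-1, 1] coords
    background_field: tuple = (5.0, 3.0, -8.0, 6.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be 3-D with at least 8 voxels per axis")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size entries must be > 0")


@dataclass
class TaskDesign:
    """Block design of the simulated task run."""

    tr_s: float = 1.0
    n_volumes: int = 140
    #: (onset_s, duration_s) pairs
    blocks: tuple = ((14.0, 14.0), (42.0, 14.0), (70.0, 14.0), (98.0, 14.0), (126.0, 14.0))
    amplitude_pct: float = 2.0
    active_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.tr_s <= 0 or self.n_volumes < 2:
            raise ValueError("invalid TR or run length")
        if self.amplitude_pct < 0:
            raise ValueError("amplitude_pct must be >= 0")
        total = self.tr_s * self.n_volumes
        for onset, dur in self.blocks:
            if onset < 0 or dur <= 0 or onset + dur > total + 1e-9:
                raise ValueError(f"block ({onset}, {dur}) outside run duration {total}s")

    def boxcar(self) -> np.ndarray:
        t = np.arange(self.n_volumes) * self.tr_s
        box = np.zeros(self.n_volumes)
        for onset, dur in self.blocks:
            box[(t >= onset) & (t < onset + dur)] = 1.0
        return box

    def regressor(self) -> np.ndarray:
        """Boxcar convolved with the canonical double-gamma HRF (unit-peak kernel)."""
        h = double_gamma_hrf(self.tr_s)
        return np.convolve(self.boxcar(), h)[: self.n_volumes]


@dataclass
class GroundTruth:
    """Everything the assessment stage may compare against."""

    tissue_labels: np.ndarray
    brain_mask: np.ndarray
    boundary_points: np.ndarray   # (M, 3) mm coordinates on the WM surface
    boundary_normals: np.ndarray  # (M, 3) outward unit normals
    active_mask: np.ndarray
    network_masks: list
    true_field: FieldOffsetMap | None = None
    true_vsm: VoxelShiftMap | None = None


def _frac_grid(spec: PhantomSpec):
    axes = [np.arange(n) / (n - 1) for n in spec.grid_shape]
    return np.meshgrid(*axes, indexing="ij")


def _mm_grid(spec: PhantomSpec):
    axes = [np.arange(n) * v for n, v in zip(spec.grid_shape, spec.voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(fr, center_frac, radii_frac):
    q = sum(((f - c) / r) ** 2 for f, c, r in zip(fr, center_frac, radii_frac))
    return q <= 1.0


def brain_mask_for(spec: PhantomSpec) -> np.ndarray:
    fr = _frac_grid(spec)
    r = spec.brain_radius_frac
    return _ellipsoid(fr, (0.5, 0.5, 0.5), (r, r, r))


def _tissue_labels(spec: PhantomSpec) -> np.ndarray:
    fr = _frac_grid(spec)
    mm = _mm_grid(spec)
    r = spec.brain_radius_frac
    brain = _ellipsoid(fr, (0.5, 0.5, 0.5), (r, r, r))
    wm = _ellipsoid(fr, (0.5, 0.5, 0.5), tuple(r * spec.wm_radius_frac for _ in range(3)))
    rim_inner = _ellipsoid(fr, (0.5, 0.5, 0.5), tuple(r * spec.csf_rim_frac for _ in range(3)))
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[brain] = LABELS["gm"]
    labels[brain & ~rim_inner] = LABELS["csf"]
    labels[wm] = LABELS["wm"]
    extent = [(n - 1) * v for n, v in zip(spec.grid_shape, spec.voxel_size)]
    for center_frac, radii_mm in spec.ventricles:
        center_mm = [c * e for c, e in zip(center_frac, extent)]
        q = sum(((g - c) / rr) ** 2 for g, c, rr in zip(mm, center_mm, radii_mm))
        labels[(q <= 1.0) & brain] = LABELS["csf"]
    return labels


def _wm_boundary(labels: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    wm = labels == LABELS["wm"]
    surface = wm & ~ndimage.binary_erosion(wm)
    smooth = ndimage.gaussian_filter(wm.astype(float), 1.2)
    grads = np.gradient(smooth, *voxel_size)
    idx = np.argwhere(surface)
    g = np.stack([gi[tuple(idx.T)] for gi in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    keep = norms > 1e-8
    idx, g, norms = idx[keep], g[keep], norms[keep]
    normals = -g / norms[:, None]  # outward: away from increasing WM fraction
    points = idx * np.asarray(voxel_size)[None, :]
    return points, normals


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Structural (T1-like) volume plus ground-truth labels and boundaries."""
    labels = _tissue_labels(spec)
    brain = labels > 0
    for name in ("csf", "gm", "wm"):
        if not np.any(labels == LABELS[name]):
            raise ValueError(f"degenerate phantom geometry: tissue class '{name}' is empty")
    rng = np.random.default_rng(spec.seed)
    structural = np.zeros(spec.grid_shape, dtype=float)
    for name, lab in LABELS.items():
        sel = labels == lab
        structural[sel] = spec.tissue_means[name]
        sd = spec.tissue_noise_sd.get(name, 0.0)
        if sd > 0:
            structural[sel] += rng.normal(0.0, sd, size=int(sel.sum()))
    structural = np.clip(structural, 0.0, None)

    points, normals = _wm_boundary(labels, spec.voxel_size)
    mm = _mm_grid(spec)
    extent = [(n - 1) * v for n, v in zip(spec.grid_shape, spec.voxel_size)]

    # activation seeded in the high-|field| region around the first blob
    blob_center = [c * e for c, e in zip(spec.sinus_blobs[0][0], extent)] if spec.sinus_blobs \
        else [0.5 * e for e in extent]
    d2 = sum((g - c) ** 2 for g, c in zip(mm, blob_center))
    active = (d2 <= 9.0 ** 2) & brain
    if not active.any():  # fall back to a central sphere
        center = [0.5 * e for e in extent]
        d2 = sum((g - c) ** 2 for g, c in zip(mm, center))
        active = (d2 <= 9.0 ** 2) & brain

    network_centers = ((0.50, 0.18, 0.62), (0.28, 0.45, 0.68), (0.72, 0.45, 0.68))
    networks = []
    for cf in network_centers:
        c_mm = [c * e for c, e in zip(cf, extent)]
        d2 = sum((g - c) ** 2 for g, c in zip(mm, c_mm))
        networks.append((d2 <= 10.0 ** 2) & brain)

    truth = GroundTruth(
        tissue_labels=labels,
        brain_mask=brain,
        boundary_points=points,
        boundary_normals=normals,
        active_mask=active,
        network_masks=networks,
    )
    return structural, truth


def make_field(spec: PhantomSpec) -> FieldOffsetMap:
    """Smooth background field plus focal Gaussian offsets, in Hz."""
    mm = _mm_grid(spec)
    extent = [(n - 1) * v for n, v in zip(spec.grid_shape, spec.voxel_size)]
    u = [2.0 * g / e - 1.0 for g, e in zip(mm, extent)]  # [-1, 1] coords
    c0, cx, cy, cz = spec.background_field
    field = c0 + cx * u[0] + cy * u[1] + cz * u[2]
    for center_frac, width_mm, amp_hz in spec.sinus_blobs:
        c_mm = [c * e for c, e in zip(center_frac, extent)]
        d2 = sum((g - c) ** 2 for g, c in zip(mm, c_mm))
        field = field + amp_hz * np.exp(-0.5 * d2 / width_mm ** 2)
    return FieldOffsetMap(field, brain_mask_for(spec))


def synth_dual_echo(structural: np.ndarray, field: FieldOffsetMap,
                    te1_s: float = 4.92e-3, te2_s: float = 7.38e-3,
                    noise_sd: float = 0.0, t2star_s: float = 0.05,
                    seed: int | None = None) -> DualEchoGRE:
    """Dual-echo GRE magnitudes and wrapped phase difference.

    The two echoes are simulated as complex signals
    ``M * exp(-TE/T2*) * exp(i * 2*pi * dB0 * TE)`` with independent complex
    Gaussian noise of standard deviation ``noise_sd`` per channel, so the
    magnitudes are Rician and the phase noise scales as 1/SNR.  The phase
    difference is returned wrapped into ``(-pi, pi]``.  Standard (single
    phase-encode per excitation) GRE images are geometrically undistorted.
    """
    if te2_s <= te1_s:
        raise ValueError("TE2 must be greater than TE1")
    rng = np.random.default_rng(seed)
    m = np.asarray(structural, dtype=float)
    db0 = field.values if isinstance(field, FieldOffsetMap) else np.asarray(field, float)
    echoes = []
    for te in (te1_s, te2_s):
        sig = m * np.exp(-te / t2star_s) * np.exp(1j * 2 * np.pi * db0 * te)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, m.shape) \
                + 1j * rng.normal(0.0, noise_sd, m.shape)
        echoes.append(sig)
    phase_diff = np.angle(echoes[1] * np.conj(echoes[0]))
    # np.angle returns [-pi, pi]; fold the closed lower edge onto +pi
    phase_diff = np.where(phase_diff <= -np.pi, np.pi, phase_diff)
    return DualEchoGRE(
        magnitude1=np.abs(echoes[0]),
        magnitude2=np.abs(echoes[1]),
        phase_diff=phase_diff,
        te1_s=te1_s,
        te2_s=te2_s,
    )


def epi_baseline(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Noise-free EPI-contrast baseline volume from the tissue labels."""
    out = np.zeros(labels.shape, dtype=float)
    for name, lab in LABELS.items():
        out[labels == lab] = spec.epi_tissue_means[name]
    return out


@dataclass
class EpiRun:
    """One simulated functional run plus its reversed-polarity calibration."""

    ap: np.ndarray          # (x, y, z, t) distorted AP series
    pa: np.ndarray          # (x, y, z, n_pa) distorted PA calibration volumes
    bold: np.ndarray        # undistorted, noise-free BOLD series
    baseline: np.ndarray    # undistorted noise-free baseline volume
    geom: EPIGeometry
    design: TaskDesign


def synth_epi_run(truth: GroundTruth, field: FieldOffsetMap, geom: EPIGeometry,
                  design: TaskDesign, spec: PhantomSpec,
                  noise_sd: float = 0.0, network_amp_pct: float = 1.0,
                  n_pa: int = 10, seed: int = 0) -> EpiRun:
    """Distorted AP 4-D series and PA calibration volumes.

    The clean series is ``baseline * (1 + task + networks)`` where the task
    term is the HRF-convolved boxcar scaled to ``design.amplitude_pct`` %
    signal change in the active mask and each network mask fluctuates with
    an independent low-frequency (< 0.1 Hz) time course of
    ``network_amp_pct`` % standard deviation.  Each volume is then warped
    with the true shift map (AP with +1 polarity; the ``n_pa`` calibration
    volumes, task-free, with -1) and Gaussian noise of ``noise_sd`` is added
    in the distorted frame.
    """
    rng = np.random.default_rng(seed)
    base = epi_baseline(truth.tissue_labels, spec)
    vsm = db0_to_vsm(field, geom)
    tcount = design.n_volumes

    modulation = np.ones(truth.tissue_labels.shape + (tcount,), dtype=float)
    active = design.active_mask if design.active_mask is not None else truth.active_mask
    reg = design.regressor()
    modulation[active] += (design.amplitude_pct / 100.0) * reg[None, :]
    for mask in truth.network_masks:
        tc = rng.standard_normal(tcount)
        tc = ndimage.gaussian_filter1d(tc, sigma=4.0 / design.tr_s, mode="reflect")
        sd = tc.std()
        if sd > 0:
            tc = tc / sd
        modulation[mask] += (network_amp_pct / 100.0) * tc[None, :]
    bold = base[..., None] * modulation

    ap_plan = PEResamplePlan(vsm, geom.with_polarity(+1), "apply", conserve_mass=True)
    pa_plan = PEResamplePlan(vsm, geom.with_polarity(-1), "apply", conserve_mass=True)
    ap = ap_plan(bold)
    if noise_sd > 0:
        ap = ap + rng.normal(0.0, noise_sd, ap.shape)
    pa_base = pa_plan(base)
    pa = np.repeat(pa_base[..., None], n_pa, axis=-1)
    if noise_sd > 0:
        pa = pa + rng.normal(0.0, noise_sd, pa.shape)

    return EpiRun(ap=ap.astype(np.float32), pa=pa.astype(np.float32),
                  bold=bold.astype(np.float32), baseline=base, geom=geom, design=design)
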