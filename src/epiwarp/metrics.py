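"""Assessment statistics for distortion correction pipelines.

Normalised mean squared error and cross-correlation between image pairs,
Dice overlap, randomized mutually-exclusive template assignment for
resting-state networks, the boundary-based-registration (BBR) contrast
cost, and per-ROI shift ranges.

Note on the nMSE normalisation: ``nmse = 2 * sum((A-B)^2) / sum(A^2 + B^2)``
over the mask.  The symmetric denominator makes the statistic symmetric in
its arguments and equal to 2 when one image is identically zero; absolute
values reported elsewhere depend on this choice.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import ndimage


def _masked_pair(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share one shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("mask is empty")
    return a[mask], b[mask]


def nmse(a, b, mask=None) -> float:
    """Symmetric normalised MSE: ``2*sum((A-B)^2) / sum(A^2 + B^2)`` over the mask."""
    av, bv = _masked_pair(a, b, mask)
    denom = float(np.sum(av * av) + np.sum(bv * bv))
    if denom == 0.0:
        raise ValueError("nMSE undefined: both images are zero on the mask")
    return 2.0 * float(np.sum((av - bv) ** 2)) / denom


def cross_correlation(a, b, mask=None) -> float:
    """Pearson correlation of the two images over the mask voxels."""
    av, bv = _masked_pair(a, b, mask)
    av = av - av.mean()
    bv = bv - bv.mean()
    sa, sb = np.sqrt(np.sum(av * av)), np.sqrt(np.sum(bv * bv))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("cross-correlation undefined: zero variance on the mask")
    return float(np.clip(np.sum(av * bv) / (sa * sb), -1.0, 1.0))


def dice(mask_a, mask_b) -> float:
    """Dice overlap ``2|A&B| / (|A|+|B|)``; 0 (with a warning) when both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        warnings.warn("Dice of two empty masks returned as 0 by convention", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / total


def threshold_component(z_map: np.ndarray, z_thresh: float = 3.0) -> np.ndarray:
    """One-sided suprathreshold mask of positive loadings: ``z > z_thresh``."""
    z_map = np.asarray(z_map, dtype=float)
    if not np.all(np.isfinite(z_map)):
        raise ValueError("z map contains non-finite values")
    return z_map > z_thresh


@dataclass
class DiceMatrix:
    """Templates x components matrix of Dice coefficients."""

    values: np.ndarray
    template_names: list | None = None
    component_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Dice matrix must be 2-D (templates x components)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("Dice entries must lie in [0, 1]")
        t, c = self.values.shape
        if self.template_names is None:
            self.template_names = [f"T{i+1}" for i in range(t)]
        if self.component_ids is None:
            self.component_ids = list(range(c))


@dataclass
class Assignment:
    """Mutually exclusive template -> component mapping."""

    mapping: dict
    mean_dice: float
    order_used: tuple


def _greedy(values: np.ndarray, order) -> tuple[dict, float]:
    t, c = values.shape
    available = np.ones(c, dtype=bool)
    mapping = {}
    total = 0.0
    for ti in order:
        row = np.where(available, values[ti], -np.inf)
        ci = int(np.argmax(row))  # argmax takes the lowest index on ties
        mapping[ti] = ci
        total += values[ti, ci]
        available[ci] = False
    return mapping, total / t


def assign_rsns(dice_matrix, max_orders: int = 10000,
                seed: int | None = None) -> Assignment:
    """Best mutually-exclusive greedy assignment over template orderings.

    Each candidate ordering assigns templates sequentially, each taking the
    highest-Dice component still unassigned.  When the number of orderings
    ``T!`` does not exceed ``max_orders`` all are enumerated
    (deterministic); otherwise ``max_orders`` random orderings are sampled
    with the given seed.  Ties between orderings keep the first one found;
    ties between components take the lowest component index.
    """
    d = dice_matrix if isinstance(dice_matrix, DiceMatrix) else DiceMatrix(np.asarray(dice_matrix))
    t, c = d.values.shape
    if c < t:
        raise ValueError(f"need at least as many components ({c}) as templates ({t})")
    if math.factorial(t) <= max_orders:
        orders = permutations(range(t))
    else:
        rng = np.random.default_rng(seed)
        orders = (tuple(rng.permutation(t)) for _ in range(max_orders))
    best = None
    for order in orders:
        mapping, mean = _greedy(d.values, order)
        if best is None or mean > best[1] + 1e-15:
            best = (mapping, mean, tuple(order))
    return Assignment(mapping=best[0], mean_dice=float(best[1]), order_used=best[2])


def bbr_cost(volume: np.ndarray, boundary_points: np.ndarray,
             normals: np.ndarray, voxel_size, offset_mm: float = 2.0,
             slope: float = 0.5) -> float:
    """Boundary contrast cost in [0, 1]; lower means better registration.

    For each WM-surface point the image is sampled at ``p -/+ offset * n``
    (inside/outside, linear interpolation).  The percent contrast
    ``Q = 100 (I_out - I_in) / (0.5(|I_out| + |I_in|) + eps)`` is softly
    clipped through ``(1 + tanh(slope * Q / 100)) / 2`` and averaged, so
    with ``slope > 0`` a bright-inside (T1-like, WM > GM) boundary scores
    toward 0 and an inverted boundary toward 1.  For EPI-like contrast
    (GM outside brighter than WM) pass a negative slope, which encodes the
    inverted expected contrast.  A uniform image scores exactly 0.5.
    Points whose samples would leave the grid are excluded; more than 50%
    exclusions raise an error.
    """
    volume = np.asarray(volume, dtype=float)
    points = np.asarray(boundary_points, dtype=float)
    normals = np.asarray(normals, dtype=float)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (volume.ndim,))
    upper = (np.asarray(volume.shape) - 1)
    samples = []
    n_excluded = 0
    coords = {}
    for sign in (-1.0, +1.0):
        p = points + sign * offset_mm * normals
        coords[sign] = p / voxel_size[None, :]
    inside = np.ones(len(points), dtype=bool)
    for sign in (-1.0, +1.0):
        cc = coords[sign]
        inside &= np.all((cc >= 0) & (cc <= upper[None, :]), axis=1)
    n_excluded = int((~inside).sum())
    if n_excluded > 0.5 * len(points):
        raise ValueError(f"{n_excluded}/{len(points)} boundary points fall outside the grid")
    i_in = ndimage.map_coordinates(volume, coords[-1.0][inside].T, order=1)
    i_out = ndimage.map_coordinates(volume, coords[+1.0][inside].T, order=1)
    q = 100.0 * (i_out - i_in) / (0.5 * (np.abs(i_out) + np.abs(i_in)) + 1e-9)
    return float(np.mean((1.0 + np.tanh(slope * q / 100.0)) / 2.0))


def vsm_roi_range(vsm, roi: np.ndarray) -> tuple[float, float]:
    """(min, max) shift in mm over the ROI voxels."""
    values = vsm.values if hasattr(vsm, "values") else np.asarray(vsm, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != values.shape:
        raise ValueError("ROI shape mismatch")
    if not roi.any():
        raise ValueError("ROI is empty")
    sel = values[roi]
    return float(sel.min()), float(sel.max())
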