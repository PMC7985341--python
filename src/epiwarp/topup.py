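"""Reversed phase-encoding (blip-up/blip-down) displacement estimation.

Two EPI images acquired with opposite PE polarities are distorted with
opposite signs, and the undistorted image lies midway between them.  The
estimator finds the shift map ``v`` (mm, on the AP ``+1`` polarity
convention) minimising

.. math:: \\tfrac12\\sum_M [U_+(AP; v) - U_-(PA; v)]^2
          + \\tfrac{\\lambda}{2}\\,\\|L c\\|^2

where ``U_+/U_-`` unwarp with ``+v`` / ``-v`` (including Jacobian intensity
modulation, so compressed regions are brightened back), ``c`` are cubic
B-spline coefficients of ``v`` on a coarse knot grid, and ``L`` is a
discrete Laplacian on the coefficients (a bending-energy surrogate).  A
Gauss-Newton scheme with line search runs coarse-to-fine over a Gaussian
smoothing pyramid; the accepted objective values are non-increasing within
each level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline
from scipy.sparse.linalg import LinearOperator, cg

from .fieldmap import brain_mask_from_magnitude
from .warp import (EPIGeometry, NonInvertibleWarpError, PEResamplePlan,
                   VoxelShiftMap)


@dataclass
class ReversedPair:
    """One AP and one PA volume sharing a grid and acquisition geometry."""

    ap_volume: np.ndarray
    pa_volume: np.ndarray
    geom: EPIGeometry  # polarity of the AP member; the PA member is its negation

    def __post_init__(self):
        self.ap_volume = np.asarray(self.ap_volume, dtype=float)
        self.pa_volume = np.asarray(self.pa_volume, dtype=float)
        if self.ap_volume.shape != self.pa_volume.shape:
            raise ValueError("AP and PA volumes must share one grid")


@dataclass
class TopupParams:
    """Estimator controls.

    ``pyramid_smooth_mm`` lists the Gaussian pre-smoothing of each level,
    coarse to fine.  ``lambda_rel`` scales the bending penalty relative to
    the data term at the level's initial iterate (normalised by the bending
    of an all-ones coefficient field), so the penalty tracks the residual
    noise floor rather than the unaligned misfit.  ``knot_spacing_mm`` sets
    the B-spline resolution of the estimated shift map;
    ``init_smooth_mm`` the pre-smoothing of the closed-form cumulative
    initialisation.
    """

    pyramid_smooth_mm: tuple = (8.0, 4.0, 2.0)
    lambda_rel: float = 0.01
    max_iter: int = 15
    tol: float = 1e-4
    knot_spacing_mm: float = 12.0
    init_smooth_mm: float = 4.0

    def __post_init__(self):
        if self.lambda_rel < 0 or self.max_iter < 1 or self.tol <= 0 \
                or self.knot_spacing_mm <= 0:
            raise ValueError("TopupParams entries must be positive")
        if any(s < 0 for s in self.pyramid_smooth_mm) or self.init_smooth_mm < 0:
            raise ValueError("pyramid smoothing must be >= 0")


@dataclass
class TopupResult:
    vsm: VoxelShiftMap
    objective_trace: list = dc_field(default_factory=list)  # one list per level
    converged: bool = True


def _spline_basis(n_vox: int, vox_mm: float, knot_mm: float) -> np.ndarray:
    """Clamped cubic B-spline design matrix (n_vox x n_coef) for one axis."""
    length = (n_vox - 1) * vox_mm
    n_seg = max(1, int(round(length / knot_mm)))
    interior = np.linspace(0.0, length, n_seg + 1)
    t = np.r_[[0.0] * 3, interior, [length] * 3]
    x = np.minimum(np.arange(n_vox) * vox_mm, length - 1e-9)
    return BSpline.design_matrix(x, t, 3).toarray()


class _SplineField:
    """Tensor-product B-spline parameterisation of a scalar 3-D field."""

    def __init__(self, grid_shape, voxel_size, knot_mm):
        self.bases = [_spline_basis(n, v, knot_mm)
                      for n, v in zip(grid_shape, voxel_size)]
        self.coef_shape = tuple(b.shape[1] for b in self.bases)

    def expand(self, c: np.ndarray) -> np.ndarray:
        bx, by, bz = self.bases
        return np.einsum("ia,jb,kc,abc->ijk", bx, by, bz, c, optimize=True)

    def adjoint(self, w: np.ndarray) -> np.ndarray:
        bx, by, bz = self.bases
        return np.einsum("ia,jb,kc,ijk->abc", bx, by, bz, w, optimize=True)


_LAP = np.zeros((3, 3, 3))
_LAP[1, 1, 1] = -6.0
for _off in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
    _LAP[_off] = 1.0


def _laplacian(c: np.ndarray) -> np.ndarray:
    # symmetric kernel + zero padding => self-adjoint
    return ndimage.correlate(c, _LAP, mode="constant")


def _cumulative_shift(ap: np.ndarray, pa: np.ndarray, geom: EPIGeometry,
                      smooth_mm: float = 4.0, eps_frac: float = 1e-3) -> np.ndarray:
    """Closed-form midway shift from cumulative line-profile matching.

    With mass-conserving distortions the cumulative intensity along each PE
    line is an invariant re-parameterised by the warp: positions holding
    equal cumulative mass in the AP and PA profiles are images of one true
    position, which lies midway between them.  Matching quantiles therefore
    recovers the shift directly.  A small intensity floor (``eps_frac`` of
    the mean) keeps the profiles strictly increasing through empty regions,
    and mild pre-smoothing suppresses noise in the quantile inversion.
    Returns the shift map in mm on the AP (+1) polarity convention.
    """
    if smooth_mm > 0:
        sig = smooth_mm / 2.35482 / geom.voxel_size_pe
        ap = ndimage.gaussian_filter(ap, sig)
        pa = ndimage.gaussian_filter(pa, sig)
    av = np.moveaxis(ap, geom.pe_axis, -1)
    moved_shape = av.shape
    av = av.reshape(-1, moved_shape[-1])
    pv = np.moveaxis(pa, geom.pe_axis, -1).reshape(-1, moved_shape[-1])
    n_lines, n = av.shape
    floor = eps_frac * max(av.mean(), 1e-30)
    zeros = np.zeros((n_lines, 1))
    ca = np.concatenate([zeros, np.cumsum(np.clip(av, 0, None) + floor, axis=1)], axis=1)
    cp = np.concatenate([zeros, np.cumsum(np.clip(pv, 0, None) + floor, axis=1)], axis=1)
    cp *= ca[:, -1:] / cp[:, -1:]
    yh = np.arange(n + 1) - 0.5
    y = np.arange(n)
    v = np.empty((n_lines, n))
    for li in range(n_lines):
        y_pa = np.interp(ca[li], cp[li], yh)  # PA position with the AP edge's mass
        y_true = 0.5 * (yh + y_pa)
        d = 0.5 * (yh - y_pa)
        v[li] = np.interp(y, y_true, d)
    v = v * geom.voxel_size_pe
    return np.moveaxis(v.reshape(moved_shape), -1, geom.pe_axis)


def _gradient_matrix(n: int) -> np.ndarray:
    """Matrix form of np.gradient along one axis (so the adjoint is exact)."""
    d = np.zeros((n, n))
    d[0, 0], d[0, 1] = -1.0, 1.0
    d[-1, -2], d[-1, -1] = -1.0, 1.0
    for i in range(1, n - 1):
        d[i, i - 1], d[i, i + 1] = -0.5, 0.5
    return d


def _apply_along(mat: np.ndarray, grid: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(grid, axis, -1)
    out = moved @ mat.T
    return np.moveaxis(out, -1, axis)


def _unwarped_pair(ap, pa, v_mm, geom):
    up = PEResamplePlan(v_mm, geom.with_polarity(+1), "unwarp", True)(ap)
    um = PEResamplePlan(v_mm, geom.with_polarity(-1), "unwarp", True)(pa)
    return up, um


def estimate_field_topup(pair: ReversedPair, params: TopupParams | None = None,
                         mask: np.ndarray | None = None) -> TopupResult:
    """Estimate the PE shift map from a reversed-polarity pair.

    Returns the shift map on the AP (+1 polarity) convention together with
    the per-level objective traces.  If the Gauss-Newton iteration stalls
    before ``max_iter`` without meeting ``tol`` the best iterate is
    returned with ``converged=False`` and a warning.
    """
    params = params or TopupParams()
    geom = pair.geom
    ap, pa = pair.ap_volume, pair.pa_volume
    if mask is None:
        mask = brain_mask_from_magnitude(0.5 * (ap + pa))
        mask = ndimage.binary_dilation(mask, iterations=3)
    w = mask.astype(float)

    sf = _SplineField(ap.shape, [geom.voxel_size_pe] * ap.ndim, params.knot_spacing_mm)
    bend_unit = float(np.sum(_laplacian(np.ones(sf.coef_shape)) ** 2))
    n_par = int(np.prod(sf.coef_shape))
    sq_bases = [b * b for b in sf.bases]

    def _diag(wgrid):
        # diagonal of S^T diag(wgrid) S via the squared basis matrices
        bx, by, bz = sq_bases
        return np.einsum("ia,jb,kc,ijk->abc", bx, by, bz, wgrid, optimize=True)

    # Weighted least-squares projection of a shift grid onto the spline
    # basis.  Shift estimates are meaningless where there is no signal, so
    # outside the mask the field is pulled (weakly) to zero, and bending
    # regularisation controls what is left of the basis null space.
    w_init = w + 0.05 * (1.0 - w)
    diag0 = _diag(w_init)
    lam0 = 1e-3 * float(diag0.max())
    mu0 = 1e-6 * float(diag0.max()) + 1e-30

    def proj_mv(x):
        xc = x.reshape(sf.coef_shape)
        hx = sf.adjoint(w_init * sf.expand(xc)) + lam0 * _laplacian(_laplacian(xc)) + mu0 * xc
        return hx.ravel()

    proj_op = LinearOperator((n_par, n_par), matvec=proj_mv)
    proj_pre = LinearOperator((n_par, n_par),
                              matvec=lambda x: x / (diag0.ravel() + lam0 * 42.0 + mu0))

    def project(v_grid: np.ndarray) -> np.ndarray:
        v_grid = np.where(mask, v_grid, 0.0)
        sol, _ = cg(proj_op, sf.adjoint(w_init * v_grid).ravel(),
                    M=proj_pre, rtol=1e-8, maxiter=400)
        return sol.reshape(sf.coef_shape)

    # closed-form midway initialisation
    c = project(_cumulative_shift(ap, pa, geom, params.init_smooth_mm))
    dmat = _gradient_matrix(ap.shape[geom.pe_axis])

    traces = []
    converged = True
    for smooth_mm in params.pyramid_smooth_mm:
        if smooth_mm > 0:
            sig = smooth_mm / 2.35482 / geom.voxel_size_pe
            a_lv = ndimage.gaussian_filter(ap, sig)
            p_lv = ndimage.gaussian_filter(pa, sig)
        else:
            a_lv, p_lv = ap, pa

        # ensure the level starts from an invertible warp (shrink toward zero)
        while True:
            try:
                up0, um0 = _unwarped_pair(a_lv, p_lv, sf.expand(c), geom)
                break
            except NonInvertibleWarpError:
                c = 0.5 * c
        data0 = 0.5 * float(np.sum(w * (up0 - um0) ** 2))
        lam = params.lambda_rel * data0 / max(bend_unit, 1e-12)

        def objective(coefs):
            v = sf.expand(coefs)
            try:
                up, um = _unwarped_pair(a_lv, p_lv, v, geom)
            except NonInvertibleWarpError:
                return np.inf, (None, None), v
            bend = float(np.sum(_laplacian(coefs) ** 2))
            data = 0.5 * float(np.sum(w * (up - um) ** 2))
            return data + 0.5 * lam * bend, (up, um), v

        def line_search(direction, obj, min_step=1.0 / 64):
            step = 1.0
            while step >= min_step:
                cand = c + step * direction
                obj_new, pair_new, v_new = objective(cand)
                if obj_new < obj:
                    return cand, obj_new, pair_new, v_new
                step *= 0.5
            return None

        obj, (up, um), v = objective(c)
        trace = [obj]
        eps = 0.25 * geom.voxel_size_pe
        for _ in range(params.max_iter):
            accepted = None
            # candidate 1: projected residual midway correction.  The
            # unwarped pair still differs by the residual distortion, and
            # cumulative matching of the pair reads it off directly.
            dv = _cumulative_shift(up, um, geom, smooth_mm=2.0)
            accepted = line_search(project(dv), obj, min_step=1.0 / 16)
            if accepted is None:
                # candidate 2: Gauss-Newton step with the full linearisation
                # of the modulated unwarp: a shift perturbation moves the
                # sampling point AND changes the Jacobian modulation, so
                # dr/dv = g1 + g2 * d/dy with g1 the uniform-shift central
                # difference and g2 the point-sampled pair intensity.
                r = up - um
                g1 = (
                    PEResamplePlan(v + eps, geom.with_polarity(+1), "unwarp", True)(a_lv)
                    - PEResamplePlan(v - eps, geom.with_polarity(+1), "unwarp", True)(a_lv)
                    - PEResamplePlan(v + eps, geom.with_polarity(-1), "unwarp", True)(p_lv)
                    + PEResamplePlan(v - eps, geom.with_polarity(-1), "unwarp", True)(p_lv)
                ) / (2.0 * eps)
                g2 = (PEResamplePlan(v, geom.with_polarity(+1), "unwarp", False)(a_lv)
                      + PEResamplePlan(v, geom.with_polarity(-1), "unwarp", False)(p_lv)) \
                    / geom.voxel_size_pe

                def jac(dv):
                    return g1 * dv + g2 * _apply_along(dmat, dv, geom.pe_axis)

                def jac_t(rr):
                    return g1 * rr + _apply_along(dmat.T, g2 * rr, geom.pe_axis)

                grad_c = sf.adjoint(jac_t(w * r)) + lam * _laplacian(_laplacian(c))
                diag_h = _diag(w * g1 * g1) + lam * 42.0  # 42 = |Laplacian kernel|^2
                mu = 1e-4 * float(diag_h.max()) + 1e-30  # Levenberg damping

                def hess_mv(x):
                    xc = x.reshape(sf.coef_shape)
                    hx = sf.adjoint(jac_t(w * jac(sf.expand(xc)))) \
                        + lam * _laplacian(_laplacian(xc)) + mu * xc
                    return hx.ravel()

                op = LinearOperator((n_par, n_par), matvec=hess_mv)
                precond = LinearOperator((n_par, n_par),
                                         matvec=lambda x: x / (diag_h.ravel() + mu))
                delta, _info = cg(op, -grad_c.ravel(), M=precond, rtol=1e-3, maxiter=80)
                accepted = line_search(delta.reshape(sf.coef_shape), obj)
            if accepted is None:
                break
            c, obj, (up, um), v = accepted
            trace.append(obj)
            if abs(trace[-2] - trace[-1]) <= params.tol * max(trace[-2], 1e-30):
                break
        else:
            converged = False
        traces.append(trace)

    if not converged:
        warnings.warn("reversed-PE estimator hit max_iter without meeting tol; "
                      "returning best iterate", stacklevel=2)
    v_final = sf.expand(c)
    return TopupResult(vsm=VoxelShiftMap(v_final, mask),
                       objective_trace=traces, converged=converged)


def correct_pair(pair: ReversedPair, vsm: VoxelShiftMap,
                 conserve_mass: bool = True):
    """Unwarp both members with the estimated shift map; return their midway mean."""
    if vsm.values.shape != pair.ap_volume.shape:
        raise ValueError("shift map grid does not match the pair")
    geom = pair.geom
    ap_c = PEResamplePlan(vsm, geom.with_polarity(+1), "unwarp", conserve_mass)(pair.ap_volume)
    pa_c = PEResamplePlan(vsm, geom.with_polarity(-1), "unwarp", conserve_mass)(pair.pa_volume)
    return ap_c, pa_c, 0.5 * (ap_c + pa_c)


def correct_series(series: np.ndarray, vsm: VoxelShiftMap, geom: EPIGeometry,
                   conserve_mass: bool = True) -> np.ndarray:
    """Apply the single estimated shift map to every volume of a 4-D series."""
    plan = PEResamplePlan(vsm, geom, "unwarp", conserve_mass)
    return plan(np.asarray(series, dtype=float))
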