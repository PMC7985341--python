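"""Desk-scale fMRI analyses: preprocessing, block-design GLM, cluster
thresholding, group maps and spatial ICA.

The GLM is ordinary least squares per voxel with a single HRF-convolved
task regressor (plus optional confounds and an intercept); t statistics are
converted to Z through the normal-quantile transform of the t tail
probability.  Cluster inference keeps 26-connected suprathreshold
components above a fixed extent (a deliberate simplification of random
field cluster p-values).  Spatial ICA concatenates runs in time,
variance-normalises voxels and runs FastICA over the spatial dimension.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import FastICA

Z_CAP = 38.0  # |Z| beyond this is numerically indistinct from a point mass


@dataclass
class GLMDesign:
    """Design matrix pieces for the single-regressor block GLM."""

    regressor: np.ndarray
    tr_s: float
    confounds: np.ndarray | None = None

    def matrix(self, n: int) -> np.ndarray:
        reg = np.asarray(self.regressor, dtype=float)
        if reg.shape[0] != n:
            raise ValueError(f"regressor length {reg.shape[0]} != series length {n}")
        cols = [reg[:, None]]
        if self.confounds is not None:
            conf = np.asarray(self.confounds, dtype=float)
            if conf.ndim == 1:
                conf = conf[:, None]
            cols.append(conf)
        cols.append(np.ones((n, 1)))
        x = np.hstack(cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return x


@dataclass
class StatMap:
    """Per-voxel Z statistics with the effective degrees of freedom."""

    z_values: np.ndarray
    df: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        check = self.z_values if self.mask is None else self.z_values[self.mask]
        if not np.all(np.isfinite(check)):
            raise ValueError("non-finite Z values inside the mask")


def double_gamma_hrf(tr_s: float, duration_s: float = 32.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalised to unit peak.

    Difference of two gamma densities with modes at ``peak_s`` and
    ``undershoot_s`` (unit dispersion) and undershoot weight
    ``1/undershoot_ratio``.
    """
    if tr_s <= 0:
        raise ValueError("TR must be > 0")
    t = np.arange(0.0, duration_s, tr_s)
    # gamma density with scale 1 has mode a-1 -> shape = delay + 1
    h = stats.gamma.pdf(t, peak_s + 1.0) - stats.gamma.pdf(t, undershoot_s + 1.0) / undershoot_ratio
    return h / h.max()


def _dct_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: components with period > cutoff."""
    k_max = int(np.floor(2.0 * n * tr_s / cutoff_s))
    i = np.arange(n)
    cols = [np.cos(np.pi * (i + 0.5) * k / n) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def preprocess(series: np.ndarray, tr_s: float, highpass_cutoff_s: float = 100.0,
               fwhm_mm: float = 4.0, voxel_size=None) -> np.ndarray:
    """High-pass filter (DCT drift removal incl. the mean) then smooth.

    ``series`` has time on the last axis.  Spatial smoothing applies a
    Gaussian of the requested FWHM to each volume when the series is on a
    spatial grid and ``fwhm_mm > 0`` (``voxel_size`` required then).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    basis = _dct_basis(n, tr_s, highpass_cutoff_s)
    x = np.column_stack([np.ones(n), basis])
    flat = series.reshape(-1, n)
    coefs, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    out = (flat.T - x @ coefs).T.reshape(series.shape)
    if fwhm_mm > 0 and series.ndim >= 3:
        if voxel_size is None:
            raise ValueError("voxel_size is required for spatial smoothing")
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (series.ndim - 1,))
        sigma = list(fwhm_mm / 2.35482 / vs) + [0.0]
        out = ndimage.gaussian_filter(out, sigma)
    return out


def t_to_z(t_values: np.ndarray, df: float) -> np.ndarray:
    """Normal-quantile transform of the t tail probability, capped at |Z_CAP|."""
    t_values = np.asarray(t_values, dtype=float)
    p = stats.t.sf(np.abs(t_values), df)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p)
    z = np.clip(z, None, Z_CAP)
    return np.sign(t_values) * z


def fit_glm(series: np.ndarray, design: GLMDesign,
            mask: np.ndarray | None = None) -> tuple[StatMap, np.ndarray]:
    """Voxel-wise OLS fit; returns the Z map and the effect (beta) map.

    ``series`` has time last.  Voxels with zero residual variance (an exact
    fit) receive the capped Z with the sign of the effect.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    x = design.matrix(n)
    rank = x.shape[1]
    df = n - rank
    if df <= 0:
        raise ValueError("not enough time points for the design")
    flat = series.reshape(-1, n).T  # (n, V)
    beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
    resid = flat - x @ beta
    sigma2 = np.sum(resid * resid, axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
    b0 = beta[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b0 / np.where(se > 0, se, 1.0), np.sign(b0) * np.inf)
    z = np.where(np.isfinite(t), t_to_z(np.where(np.isfinite(t), t, 0.0), df),
                 np.sign(b0) * Z_CAP)
    shape = series.shape[:-1]
    return StatMap(z.reshape(shape), df=df, mask=mask), b0.reshape(shape)


def cluster_threshold(z_map, z_thresh: float = 2.5,
                      min_extent_vox: int = 10) -> np.ndarray:
    """26-connected components of ``Z > z_thresh`` with size >= min_extent."""
    z = z_map.z_values if isinstance(z_map, StatMap) else np.asarray(z_map, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z map contains non-finite values")
    supra = z > z_thresh
    if not supra.any():
        return supra
    structure = np.ones((3,) * z.ndim, dtype=bool)
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return supra
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_extent_vox
    return keep[labels]


def group_map(subject_effect_maps) -> StatMap:
    """Fixed-effects averaging within subject, one-sample t across subjects.

    Each entry is either one effect map or a sequence of per-run maps that
    are first averaged.  Voxels with zero between-subject variance are
    flagged with a warning; they get Z = 0 where the mean is also zero and
    the capped Z otherwise.
    """
    subj = []
    for m in subject_effect_maps:
        if isinstance(m, np.ndarray):
            subj.append(np.asarray(m, dtype=float))
        else:
            subj.append(np.mean([np.asarray(r, dtype=float) for r in m], axis=0))
    n = len(subj)
    if n < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    stack = np.stack(subj)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} voxel(s) have zero between-subject "
                      "variance; their t statistic is undefined", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    z = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * Z_CAP),
                 t_to_z(np.where(zero_var, 0.0, t), n - 1))
    return StatMap(z, df=n - 1)


def extract_components(runs, n_components: int, mask: np.ndarray | None = None,
                       seed: int = 0, max_iter: int = 1000) -> list:
    """Group spatial ICA: concatenate runs in time, FastICA over voxels.

    ``runs`` is a sequence of arrays with time on the last axis (4-D grids
    or 2-D ``(V, T)``).  Voxel time series are variance-normalised before
    decomposition.  Each component map is z-scored and sign-fixed so its
    spatial skewness is non-negative.  Returns one map per component on the
    input grid (zeros outside the mask).
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    spatial_shape = runs[0].shape[:-1]
    if mask is None:
        mask = np.ones(spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    data = np.concatenate([r[mask] for r in runs], axis=-1)  # (V, T_total)
    t_total = data.shape[1]
    if n_components >= t_total:
        raise ValueError(f"n_components ({n_components}) must be < total time points ({t_total})")
    data = data - data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1)
    data = data / np.where(sd > 0, sd, 1.0)[:, None]
    ica = FastICA(n_components=n_components, random_state=seed,
                  max_iter=max_iter, tol=1e-5, whiten="unit-variance")
    sources = ica.fit_transform(data)  # (V, K): spatial maps
    maps = []
    for k in range(n_components):
        s = sources[:, k]
        s = (s - s.mean()) / (s.std() + 1e-30)
        if stats.skew(s) < 0:
            s = -s
        full = np.zeros(spatial_shape, dtype=float)
        full[mask] = s
        maps.append(full)
    return maps
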