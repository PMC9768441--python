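"""Task GLM: design construction, smoothing, high-pass filtering, fitting,
contrast Z maps and thresholding.

The voxelwise model is ``b = Xβ + ε`` with ``X`` holding HRF-convolved unit
boxcars (one per condition), discrete-cosine drift columns for all periods at
or above the high-pass cutoff, and an intercept.  Contrast t statistics are
converted to Z scores by probit-matching the t CDF at the model's degrees of
freedom.  Family-wise control replaces random-field theory with a Bonferroni
voxel threshold over the brain mask plus a minimum cluster extent
(26-connected components); a circular-shift maximum-statistic permutation
threshold is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    Bold4D,
    Cluster,
    DataError,
    DesignMatrix,
    NumericalError,
    StatMap,
    TaskDesign,
)
from .hrf import HRF_PARAMS, canonical_hrf, condition_regressor

__all__ = [
    "canonical_hrf",
    "dct_drift_basis",
    "build_design",
    "smooth",
    "GaussianSmoother",
    "highpass",
    "HighPassFilter",
    "FirstLevelGLM",
    "GLMFit",
    "fit_glm",
    "contrast_zmap",
    "threshold_map",
    "permutation_null_max_z",
    "percent_signal_change",
    "t_to_z",
]

_Z_CLIP = 38.0  # |Z| cap; beyond this the normal tail underflows


def dct_drift_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """DCT-II drift columns for all periods >= ``cutoff`` seconds.

    Column k (k = 1..floor(2·T·tr/cutoff)) is cos(π(2i+1)k / 2T), unit-norm.
    """
    if cutoff <= 2 * tr:
        raise DataError("high-pass cutoff must exceed 2·TR")
    n_k = int(np.floor(2 * n_volumes * tr / cutoff))
    i = np.arange(n_volumes)
    cols = [np.cos(np.pi * (2 * i + 1) * k / (2 * n_volumes)) for k in range(1, n_k + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def build_design(
    design: TaskDesign,
    hp_cutoff: float | None = None,
    tr: float | None = None,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """T×K design: one convolved boxcar per condition, DCT drift, intercept.

    A declared condition with no events yields a warning and an all-zero
    column that is kept (so contrast indexing is stable) but excluded from
    the rank check.
    """
    tr = tr if tr is not None else design.tr
    t = n_volumes if n_volumes is not None else design.run_length
    cols, labels, roles = [], [], []
    for cond in design.conditions:
        reg = condition_regressor(design, cond)
        if not reg.any():
            warnings.warn(f"condition {cond!r} has no events; zero column kept",
                          UserWarning, stacklevel=2)
        cols.append(reg)
        labels.append(cond)
        roles.append("task")
    if hp_cutoff is not None:
        drift = dct_drift_basis(t, tr, hp_cutoff)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            labels.append(f"drift_{k + 1}")
            roles.append("drift")
    cols.append(np.ones(t))
    labels.append("intercept")
    roles.append("intercept")
    matrix = np.column_stack(cols)

    nonzero = [i for i in range(matrix.shape[1]) if matrix[:, i].any()]
    sub = matrix[:, nonzero]
    rank = np.linalg.matrix_rank(sub)
    if rank < sub.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(sub, pivoting=True, mode="economic")
        bad = [labels[nonzero[i]] for i in sorted(piv[rank:])]
        raise NumericalError(f"design matrix is rank deficient; collinear: {bad}")
    return DesignMatrix(matrix=matrix, labels=labels, roles=roles, tr=tr,
                        hp_cutoff=hp_cutoff, hrf_params=dict(HRF_PARAMS))


class GaussianSmoother(BaseEstimator, TransformerMixin):
    """Isotropic Gaussian spatial smoothing (FWHM in mm), mask-renormalized.

    Within the brain mask the kernel is renormalized (smooth(data·mask) /
    smooth(mask)) so edge voxels are not diluted by out-of-brain zeros;
    voxels outside the mask pass through unchanged.
    """

    def __init__(self, fwhm: float = 3.0):
        self.fwhm = fwhm

    def fit(self, bold: Bold4D, y: None = None) -> "GaussianSmoother":
        if self.fwhm < 0:
            raise DataError("FWHM must be >= 0")
        return self

    def transform(self, bold: Bold4D) -> Bold4D:
        if self.fwhm == 0:
            return bold
        sigma_mm = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = tuple(sigma_mm / v for v in bold.voxel_size)
        if bold.mask is None:
            out = ndimage.gaussian_filter(bold.data, sigma=sigma_vox + (0.0,))
            return bold.with_data(out)
        m = bold.mask.astype(float)
        num = ndimage.gaussian_filter(bold.data * m[..., None], sigma=sigma_vox + (0.0,))
        den = ndimage.gaussian_filter(m, sigma=sigma_vox)
        out = bold.data.copy()
        inside = bold.mask
        out[inside] = num[inside] / den[inside, None]
        return bold.with_data(out)


def smooth(bold: Bold4D, fwhm: float = 3.0) -> Bold4D:
    return GaussianSmoother(fwhm=fwhm).fit(bold).transform(bold)


class HighPassFilter(BaseEstimator, TransformerMixin):
    """Project out the DCT drift subspace below 1/cutoff; the mean is kept
    (drift columns are orthogonal to the constant)."""

    def __init__(self, cutoff: float):
        self.cutoff = cutoff

    def fit(self, bold: Bold4D, y: None = None) -> "HighPassFilter":
        self.basis_ = dct_drift_basis(bold.n_volumes, bold.tr, self.cutoff)
        return self

    def transform(self, bold: Bold4D) -> Bold4D:
        d = self.basis_
        if d.shape[1] == 0:
            return bold
        t = bold.n_volumes
        flat = bold.data.reshape(-1, t).T
        fitted = d @ (d.T @ flat)  # unit-norm orthogonal columns
        return bold.with_data((flat - fitted).T.reshape(bold.data.shape))


def highpass(bold: Bold4D, cutoff: float) -> Bold4D:
    return HighPassFilter(cutoff=cutoff).fit(bold).transform(bold)


@dataclass
class GLMFit:
    """Voxelwise OLS fit: beta maps, residual variance, degrees of freedom."""

    beta: np.ndarray        # (X, Y, Z, K)
    sigma2: np.ndarray      # (X, Y, Z) residual variance SS_res / dof
    dof: int
    design: DesignMatrix
    mask: np.ndarray
    xtx_inv: np.ndarray     # pseudo-inverse of X'X (K, K)


class FirstLevelGLM(BaseEstimator):
    """Voxelwise OLS of a BOLD run on a task design.

    Attributes (after ``fit``): ``beta_``, ``sigma2_``, ``dof_``,
    ``xtx_inv_``.  ``contrast`` returns an unthresholded Z map.
    """

    def __init__(self, design: DesignMatrix):
        self.design = design

    def fit(self, bold: Bold4D, y: None = None) -> "FirstLevelGLM":
        x = self.design.matrix
        t, k = x.shape
        if bold.n_volumes != t:
            raise DataError("design and data have different numbers of volumes")
        rank = np.linalg.matrix_rank(x)
        if t <= rank:
            raise DataError("need more volumes than design rank")
        flat = bold.data.reshape(-1, t).T
        beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
        resid = flat - x @ beta
        dof = t - rank
        sigma2 = (resid**2).sum(axis=0) / dof
        shape = bold.shape
        self.beta_ = beta.T.reshape(shape + (k,))
        self.sigma2_ = sigma2.reshape(shape)
        self.dof_ = int(dof)
        self.xtx_inv_ = np.linalg.pinv(x.T @ x)
        self.mask_ = bold.mask if bold.mask is not None else np.ones(shape, bool)
        return self

    @property
    def fit_(self) -> GLMFit:
        return GLMFit(beta=self.beta_, sigma2=self.sigma2_, dof=self.dof_,
                      design=self.design, mask=self.mask_, xtx_inv=self.xtx_inv_)

    def contrast(self, contrast: np.ndarray | dict[str, float]) -> StatMap:
        return contrast_zmap(self.fit_, contrast)


def fit_glm(bold: Bold4D, design: DesignMatrix) -> GLMFit:
    """Functional wrapper: voxelwise OLS fit of ``bold`` on ``design``."""
    return FirstLevelGLM(design).fit(bold).fit_


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Probit-match t scores at ``dof`` onto standard-normal Z, sign-symmetric."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    # work on the upper tail for numerical accuracy at large |t|
    z[pos] = -stats.norm.ppf(stats.t.sf(t[pos], dof))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], dof))
    return np.clip(z, -_Z_CLIP, _Z_CLIP)


def contrast_zmap(fit: GLMFit, contrast: np.ndarray | dict[str, float]) -> StatMap:
    """Z map for a contrast: t = c'β / sqrt(σ̂² c'(X'X)⁻¹c), probit-matched.

    Zero-variance voxels get Z = 0.
    """
    if isinstance(contrast, dict):
        contrast = fit.design.task_contrast(contrast)
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.design.n_columns,):
        raise DataError("contrast length does not match the design")
    eff = fit.beta @ c
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0), 0.0)
    z = t_to_z(t, fit.dof)
    return StatMap(z=z, contrast=c, dof=fit.dof, mask=fit.mask)


def percent_signal_change(fit: GLMFit, label: str) -> np.ndarray:
    """Peak % signal change map for one task column: β·max(column)/β₀ × 100."""
    k = fit.design.column_index(label)
    k0 = fit.design.column_index("intercept")
    col_peak = fit.design.matrix[:, k].max()
    with np.errstate(divide="ignore", invalid="ignore"):
        base = fit.beta[..., k0]
        out = np.where(base != 0, fit.beta[..., k] * col_peak / np.where(base != 0, base, 1.0) * 100.0, 0.0)
    return out


def threshold_map(
    stat_map: StatMap,
    voxel_alpha: float = 0.05,
    cluster_min: int = 2,
    voxel_threshold: float | None = None,
) -> StatMap:
    """Bonferroni-threshold a Z map and extract 26-connected clusters.

    The voxel threshold is the upper ``voxel_alpha / n_mask_voxels`` normal
    quantile unless an explicit ``voxel_threshold`` is given (e.g. from a
    permutation maximum-statistic null).  Clusters smaller than
    ``cluster_min`` voxels are discarded; the cluster list is sorted by peak
    Z descending, ties broken by size then lexicographic peak coordinate.
    """
    if stat_map.thresholded:
        raise DataError("map is already thresholded")
    mask = np.asarray(stat_map.mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise DataError("empty mask")
    if voxel_threshold is None:
        voxel_threshold = float(stats.norm.isf(voxel_alpha / n))
    supra = (stat_map.z > voxel_threshold) & mask
    labeled, n_comp = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        voxels = np.argwhere(labeled == comp)
        if voxels.shape[0] < cluster_min:
            continue
        zvals = stat_map.z[tuple(voxels.T)]
        peak_i = int(np.argmax(zvals))
        # deterministic peak among ties: argwhere is lexicographic already
        clusters.append(Cluster(voxels=voxels, peak_z=float(zvals[peak_i]),
                                peak_voxel=tuple(int(v) for v in voxels[peak_i]),
                                size=int(voxels.shape[0])))
    clusters.sort(key=lambda c: (-c.peak_z, -c.size, c.peak_voxel))
    return StatMap(z=stat_map.z.copy(), contrast=stat_map.contrast, dof=stat_map.dof,
                   mask=stat_map.mask, thresholded=True,
                   voxel_threshold=voxel_threshold, clusters=clusters)


def permutation_null_max_z(
    bold: Bold4D,
    design: DesignMatrix,
    contrast: np.ndarray | dict[str, float],
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Maximum-statistic null via circular time shifts of the task columns.

    Each permutation circularly shifts all task columns by a common random
    offset (breaking the task/data alignment while preserving the regressors'
    autocorrelation), refits, and records the in-mask maximum Z.  The 95th
    percentile of the returned distribution is a FWE threshold alternative to
    Bonferroni.
    """
    rng = np.random.default_rng(seed)
    t = design.matrix.shape[0]
    task_idx = [i for i, r in enumerate(design.roles) if r == "task"]
    out = np.empty(n_perm)
    for p in range(n_perm):
        shift = int(rng.integers(1, t))
        m = design.matrix.copy()
        m[:, task_idx] = np.roll(m[:, task_idx], shift, axis=0)
        perm_design = DesignMatrix(matrix=m, labels=design.labels, roles=design.roles,
                                   tr=design.tr, hp_cutoff=design.hp_cutoff,
                                   hrf_params=design.hrf_params)
        fit = fit_glm(bold, perm_design)
        zmap = contrast_zmap(fit, contrast)
        out[p] = zmap.z[fit.mask].max()
    return out
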