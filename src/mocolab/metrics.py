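"""Head-motion quantification: FD, DVARS, outlier detection, motion R².

Framewise displacement (FD) summarizes instantaneous head motion from the six
rigid-body parameters as the L1 norm of their backward differences, with
rotational differences converted to millimetres of arc on a sphere of
``rotation_radius`` mm (default 50, a standard approximation of the head).
DVARS summarizes instantaneous intensity change from the image itself: the
spatial RMS over the brain of the temporal backward difference, reported here
in % ΔBOLD of the run's typical intensity.  Motion outliers are flagged by a
fixed FD threshold (default 0.5 mm, strict inequality) or by a per-run
boxplot rule on DVARS (above the 75th percentile plus 1.5 IQR).

The adjusted R² statistic quantifies how much of the mean BOLD signal's
variance a motion-regressor set explains, penalized for the number of
regressors P: ``1 - (N-1)/(N-P-1) * SS_res/SS_tot``.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .containers import (
    Bold4D,
    DataError,
    DvarsSeries,
    FDSeries,
    MotionSummary,
    MotionTrace,
    NumericalError,
    OutlierMask,
)

__all__ = [
    "framewise_displacement",
    "mean_fd_variants",
    "detect_outliers_fd",
    "dvars",
    "detect_outliers_dvars",
    "motion_variance_explained",
    "mean_bold_signal",
    "summarize_motion",
]


def framewise_displacement(
    trace: MotionTrace | np.ndarray, rotation_radius: float = 50.0
) -> FDSeries:
    """FD_i = Σ|Δd| over translations + radius·Σ|Δangle| over rotations; FD_0 = 0."""
    params = trace.params if isinstance(trace, MotionTrace) else np.asarray(trace, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise DataError("expected a T x 6 motion-parameter array")
    if params.shape[0] < 2:
        raise DataError("FD needs at least two volumes")
    if not np.all(np.isfinite(params)):
        raise DataError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + rotation_radius * diffs[:, 3:].sum(axis=1)
    return FDSeries(values=fd, rotation_radius=rotation_radius)


def mean_fd_variants(
    fd: FDSeries, mask: OutlierMask
) -> tuple[float, float | None, float | None]:
    """(meanFD, meanFD', meanFD''): all frames, non-outlier frames, outlier frames.

    An empty subset's mean is reported as None.
    """
    values = fd.values
    flags = mask.flags
    if values.shape[0] != flags.shape[0]:
        raise DataError("FD series and outlier mask lengths differ")
    mean_fd = float(values.mean())
    prime = float(values[~flags].mean()) if (~flags).any() else None
    doubleprime = float(values[flags].mean()) if flags.any() else None
    return mean_fd, prime, doubleprime


def detect_outliers_fd(fd: FDSeries, threshold: float = 0.5) -> OutlierMask:
    """Flag frames with FD strictly above ``threshold`` mm."""
    if threshold <= 0:
        raise ValueError("FD threshold must be positive")
    return OutlierMask(flags=fd.values > threshold, metric="fd",
                       threshold=threshold, units="mm")


def dvars(bold: Bold4D, mask: np.ndarray | None = None) -> DvarsSeries:
    """Spatial RMS of the temporal backward difference, in % ΔBOLD.

    The raw RMS is divided by the median in-mask intensity of the temporal
    mean image and multiplied by 100; the boxplot detection rule is invariant
    to this scaling, so it affects reporting only.  DVARS_0 = 0.
    """
    m = mask if mask is not None else bold.mask
    if m is None:
        m = np.ones(bold.shape, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if not m.any():
        raise DataError("empty brain mask")
    ts = bold.data[m]  # (n_voxels, T)
    diffs = np.diff(ts, axis=1)
    values = np.zeros(bold.n_volumes)
    values[1:] = np.sqrt(np.mean(diffs**2, axis=0))
    scale = float(np.median(ts.mean(axis=1)))
    if scale <= 0:
        raise DataError("non-positive median intensity; cannot scale DVARS")
    return DvarsSeries(values=values / scale * 100.0)


def detect_outliers_dvars(dv: DvarsSeries) -> OutlierMask:
    """Boxplot rule: flag frames strictly above P75 + 1.5·IQR of the run.

    Percentiles use linear interpolation between order statistics.
    """
    values = dv.values
    if values.shape[0] < 4:
        raise DataError("DVARS outlier detection needs at least 4 volumes")
    p25, p75 = np.percentile(values, [25, 75])
    threshold = p75 + 1.5 * (p75 - p25)
    return OutlierMask(flags=values > threshold, metric="dvars",
                       threshold=float(threshold), units="%dBOLD")


def _check_rank(x: np.ndarray, labels: list[str] | None) -> None:
    """Raise NumericalError naming collinear columns if x is rank deficient."""
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = linalg.qr(x, pivoting=True, mode="economic")
        bad = sorted(piv[rank:])
        names = ([labels[i] for i in bad] if labels is not None
                 else [f"column {i}" for i in bad])
        raise NumericalError(f"regressors are rank deficient; collinear: {names}")


def motion_variance_explained(
    mean_bold: np.ndarray,
    regressors: np.ndarray,
    labels: list[str] | None = None,
    adjusted: bool = True,
) -> float:
    """R² of the mean BOLD signal regressed on motion regressors.

    By default the coefficient of determination is adjusted for the degrees
    of freedom, ``1 - (N-1)/(N-P-1) · SS_res/SS_tot``; ``adjusted=False``
    returns the plain ``1 - SS_res/SS_tot`` (monotone under nested regressor
    sets).  An explicit intercept is always included and not counted in P;
    SS_tot is taken about the mean of ``mean_bold``.
    """
    b = np.asarray(mean_bold, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(regressors, dtype=float))
    if x.shape[0] != b.shape[0]:
        x = x.T
    n, p = x.shape
    if b.shape[0] != n:
        raise DataError("mean_bold and regressors have incompatible lengths")
    if n <= p + 1:
        raise DataError(f"need N > P + 1 (got N={n}, P={p})")
    xc = x - x.mean(axis=0)
    _check_rank(xc, labels)
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, b, rcond=None)
    resid = b - design @ beta
    ss_res = float(resid @ resid)
    centered = b - b.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0:
        raise DataError("mean BOLD signal is constant; R² undefined")
    if not adjusted:
        return 1.0 - ss_res / ss_tot
    return 1.0 - (n - 1) / (n - p - 1) * ss_res / ss_tot


def mean_bold_signal(bold: Bold4D, mask: np.ndarray | None = None) -> np.ndarray:
    """Length-T spatial mean of the in-mask BOLD signal."""
    m = mask if mask is not None else bold.mask
    if m is None:
        m = np.ones(bold.shape, dtype=bool)
    return bold.data[np.asarray(m, bool)].mean(axis=0)


def summarize_motion(
    fd: FDSeries, mask: OutlierMask, r2adj: dict[str, float] | None = None
) -> MotionSummary:
    """Bundle the three FD means, the spike count and R² values for reporting."""
    mean_fd, prime, doubleprime = mean_fd_variants(fd, mask)
    return MotionSummary(
        mean_fd=mean_fd,
        mean_fd_prime=prime,
        mean_fd_doubleprime=doubleprime,
        n_spikes=mask.n_outliers,
        r2adj=dict(r2adj or {}),
    )
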