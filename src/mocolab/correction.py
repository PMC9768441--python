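"""Motion-correction strategies: nuisance regression, scrubbing, interpolation.

Nine models are compared downstream: a realign-only control, plain 6- or
24-parameter nuisance regression, either parameter set plus scan-nulling
(scrubbing) regressors for outliers detected by FD or by DVARS, and either
parameter set plus temporal interpolation of FD-detected outlier volumes.

Scrubbing adds one one-hot column per flagged volume to the nuisance matrix;
ordinary least squares then absorbs the flagged volume entirely, so the
residual there equals the voxel mean exactly.  Interpolation instead replaces
flagged volumes by values interpolated in time from the nearest non-flagged
neighbors, after the motion-parameter regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    Bold4D,
    ConfigurationError,
    DataError,
    MotionTrace,
    NumericalError,
    OutlierMask,
)
from .metrics import (
    detect_outliers_dvars,
    detect_outliers_fd,
    dvars,
    framewise_displacement,
)
from .realign import expand_mp

__all__ = [
    "build_scrubbing_regressors",
    "NuisanceRegressor",
    "nuisance_regression",
    "interpolate_outliers",
    "OutlierInterpolator",
    "NuisanceModel",
    "assemble_model",
    "OUTLIER_METHODS",
]

OUTLIER_METHODS = ("none", "scrub_fd", "scrub_dvars", "interp")


def build_scrubbing_regressors(mask: OutlierMask) -> np.ndarray:
    """T×S scan-nulling matrix: one one-hot column per flagged volume,
    columns in ascending volume order."""
    t = mask.flags.shape[0]
    idx = mask.indices
    out = np.zeros((t, idx.size))
    out[idx, np.arange(idx.size)] = 1.0
    return out


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """OLS removal of nuisance time courses from voxel time series.

    Operates on a (T, n_voxels) matrix.  An intercept is always included; the
    residuals are returned with each voxel's temporal mean added back so the
    output stays on the input intensity scale.  The same pseudoinverse is
    reused across voxels.

    Parameters
    ----------
    confounds : ndarray (T, K)
        Nuisance columns (motion parameters, scrubbing regressors, ...).
    labels : list of str, optional
        Column names used in rank-deficiency diagnostics.
    """

    def __init__(self, confounds: np.ndarray, labels: list[str] | None = None):
        self.confounds = confounds
        self.labels = labels

    def fit(self, X: np.ndarray, y: None = None) -> "NuisanceRegressor":
        X = np.asarray(X, dtype=float)
        conf = np.atleast_2d(np.asarray(self.confounds, dtype=float))
        if conf.shape[0] != X.shape[0]:
            conf = conf.T
        t, k = conf.shape
        if X.shape[0] != t:
            raise DataError("confounds and data have different numbers of volumes")
        if t <= k + 1:
            raise DataError(f"need T > K + 1 (T={t}, K={k})")
        # constant (incl. all-zero) confounds carry no information beyond the
        # intercept: drop them so e.g. a motion-free trace degrades gracefully
        keep = conf.std(axis=0) > 1e-12
        self.dropped_ = [
            (self.labels[i] if self.labels is not None else f"confound_{i}")
            for i in np.flatnonzero(~keep)
        ]
        conf = conf[:, keep]
        if self.labels is not None:
            self._kept_labels = [l for l, k_ in zip(self.labels, keep) if k_]
        else:
            self._kept_labels = None
        k = conf.shape[1]
        design = np.column_stack([np.ones(t), conf])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            from scipy.linalg import qr

            _, _, piv = qr(design, pivoting=True, mode="economic")
            labels = ["intercept"] + (
                self._kept_labels if self._kept_labels is not None
                else [f"confound_{i}" for i in range(k)]
            )
            bad = sorted(piv[rank:])
            raise NumericalError(
                f"nuisance design is rank deficient; collinear: {[labels[i] for i in bad]}"
            )
        self.design_ = design
        self.pinv_ = np.linalg.pinv(design)
        self.n_confounds_ = k
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.design_.shape[0]:
            raise DataError("data length does not match fitted design")
        mean = X.mean(axis=0)
        centered = X - mean
        beta = self.pinv_ @ centered
        return centered - self.design_ @ beta + mean


def nuisance_regression(
    bold: Bold4D, confounds: np.ndarray, labels: list[str] | None = None
) -> Bold4D:
    """Voxelwise OLS residuals of the BOLD series on the confound columns,
    with each voxel's temporal mean added back."""
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t).T  # (T, n_voxels)
    reg = NuisanceRegressor(confounds=confounds, labels=labels).fit(flat)
    cleaned = reg.transform(flat)
    return bold.with_data(cleaned.T.reshape(bold.data.shape))


def _interp_weights(t: int, good: np.ndarray) -> list[tuple[int, float]]:
    """(frame, weight) pairs reconstructing flagged frame t from good frames."""
    before = good[good < t]
    after = good[good > t]
    if before.size and after.size:
        a, b = int(before[-1]), int(after[0])
        w = (t - a) / (b - a)
        return [(a, 1.0 - w), (b, w)]
    if before.size:  # trailing run of flags: copy nearest preceding good frame
        return [(int(before[-1]), 1.0)]
    return [(int(after[0]), 1.0)]  # leading run: copy nearest following


class OutlierInterpolator(BaseEstimator, TransformerMixin):
    """Replace flagged volumes by temporal interpolation from good neighbors.

    ``kind="linear"`` interpolates linearly between the nearest preceding and
    following non-flagged volumes (runs of consecutive flags form a ramp);
    ``kind="nearest"`` copies the nearest good volume (ties go to the
    preceding one).  Leading/trailing flagged volumes copy the nearest good
    volume in either mode.
    """

    def __init__(self, mask: OutlierMask, kind: str = "linear"):
        self.mask = mask
        self.kind = kind

    def fit(self, X: np.ndarray | None = None, y: None = None) -> "OutlierInterpolator":
        if self.kind not in ("linear", "nearest"):
            raise ConfigurationError(f"unknown interpolation kind {self.kind!r}")
        flags = self.mask.flags
        if flags.all():
            raise DataError("all volumes flagged; nothing to interpolate from")
        self.good_ = np.flatnonzero(~flags)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """X is (T, n_voxels); returns a copy with flagged rows replaced."""
        X = np.asarray(X, dtype=float)
        flags = self.mask.flags
        if X.shape[0] != flags.shape[0]:
            raise DataError("data length does not match outlier mask")
        out = X.copy()
        for t in self.mask.indices:
            pairs = _interp_weights(int(t), self.good_)
            if self.kind == "nearest" and len(pairs) == 2:
                (a, wa), (b, wb) = pairs
                pairs = [(a, 1.0)] if wa >= wb else [(b, 1.0)]
            out[t] = sum(w * X[f] for f, w in pairs)
        return out


def interpolate_outliers(bold: Bold4D, mask: OutlierMask, kind: str = "linear") -> Bold4D:
    """Volume-level wrapper around :class:`OutlierInterpolator`."""
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t).T
    interp = OutlierInterpolator(mask=mask, kind=kind).fit()
    fixed = interp.transform(flat)
    return bold.with_data(fixed.T.reshape(bold.data.shape))


@dataclass
class NuisanceModel:
    """Provenance of one correction model: regressor matrix, roles, outliers."""

    model_id: str
    mp_order: int | None
    outlier_method: str
    regressors: np.ndarray
    labels: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    outlier_mask: OutlierMask | None = None
    interpolation: str | None = None

    @property
    def n_columns(self) -> int:
        return self.regressors.shape[1] if self.regressors.size else 0


def _model_id(mp_order: int | None, outlier_method: str) -> str:
    if mp_order is None:
        return "realign_only"
    suffix = {"none": "", "scrub_fd": "_fd", "scrub_dvars": "_dvars",
              "interp": "_interp"}[outlier_method]
    return f"mp{mp_order}{suffix}"


def assemble_model(
    trace: MotionTrace,
    bold: Bold4D,
    mp_order: int | None,
    outlier_method: str = "none",
    fd_threshold: float = 0.5,
    rotation_radius: float = 50.0,
    interpolation: str = "linear",
) -> tuple[Bold4D, NuisanceModel]:
    """Apply one of the nine correction models to a realigned series.

    ``mp_order=None`` with ``outlier_method="none"`` is the realign-only
    control (data pass through untouched).  Scrub models regress motion
    parameters plus one-hot outlier columns; interp models regress the motion
    parameters first and then interpolate FD-detected outlier volumes
    (outliers for interpolation are always FD > ``fd_threshold``).
    """
    if outlier_method not in OUTLIER_METHODS:
        raise ConfigurationError(f"unknown outlier method {outlier_method!r}")
    if mp_order is None:
        if outlier_method != "none":
            raise ConfigurationError("outlier handling requires motion parameters")
        model = NuisanceModel(model_id="realign_only", mp_order=None,
                              outlier_method="none",
                              regressors=np.empty((bold.n_volumes, 0)))
        return bold, model

    mps = expand_mp(trace, mp_order)
    labels = list(mps.labels)
    roles = ["motion"] * mp_order
    regressors = mps.matrix
    outlier_mask: OutlierMask | None = None

    if outlier_method in ("scrub_fd", "scrub_dvars"):
        if outlier_method == "scrub_fd":
            fd = framewise_displacement(trace, rotation_radius=rotation_radius)
            outlier_mask = detect_outliers_fd(fd, threshold=fd_threshold)
        else:
            outlier_mask = detect_outliers_dvars(dvars(bold))
        scrub = build_scrubbing_regressors(outlier_mask)
        regressors = np.hstack([regressors, scrub])
        labels += [f"scrub_{i}" for i in outlier_mask.indices]
        roles += ["scrub"] * scrub.shape[1]
        cleaned = nuisance_regression(bold, regressors, labels=labels)
    elif outlier_method == "interp":
        cleaned = nuisance_regression(bold, regressors, labels=labels)
        fd = framewise_displacement(trace, rotation_radius=rotation_radius)
        outlier_mask = detect_outliers_fd(fd, threshold=fd_threshold)
        if outlier_mask.n_outliers:
            cleaned = interpolate_outliers(cleaned, outlier_mask, kind=interpolation)
    else:
        cleaned = nuisance_regression(bold, regressors, labels=labels)

    model = NuisanceModel(
        model_id=_model_id(mp_order, outlier_method),
        mp_order=mp_order,
        outlier_method=outlier_method,
        regressors=regressors,
        labels=labels,
        roles=roles,
        outlier_mask=outlier_mask,
        interpolation=interpolation if outlier_method == "interp" else None,
    )
    return cleaned, model
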