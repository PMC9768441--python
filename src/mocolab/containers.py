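"""In-memory containers for the motion-correction pipeline.

The pipeline passes five kinds of objects between stages: the 4D BOLD grid
(:class:`Bold4D`), rigid-body motion parameters (:class:`MotionTrace`), task
timing (:class:`TaskDesign`), per-volume scalar motion metrics
(:class:`FDSeries`, :class:`DvarsSeries`, :class:`OutlierMask`), and GLM
outputs (:class:`DesignMatrix`, :class:`StatMap`).  All are thin dataclasses
around numpy arrays; validation happens at construction so downstream code
can assume shapes and units are coherent.

Units convention: translations in mm, rotations in radians (pitch, yaw, roll
about the x, y, z axes), time in seconds, intensities in arbitrary scanner
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskDesign",
    "PhantomSpec",
    "ActivationROI",
    "MotionTrace",
    "Bold4D",
    "FDSeries",
    "DvarsSeries",
    "OutlierMask",
    "MotionSummary",
    "DesignMatrix",
    "Cluster",
    "StatMap",
    "QualityMetrics",
]


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (unknown preset, bad amplitude...)."""


class DataError(ValueError):
    """Input data violate a precondition (non-finite values, empty mask...)."""


class NumericalError(ArithmeticError):
    """A computation cannot proceed numerically (rank deficiency...)."""


@dataclass
class TaskDesign:
    """Block/event timing for one functional run.

    ``events`` holds ``(condition, onset_s, duration_s)`` triples.  Onsets are
    relative to the first volume; the run spans ``run_length * tr`` seconds.
    """

    conditions: list[str]
    events: list[tuple[str, float, float]]
    run_length: int
    tr: float

    def __post_init__(self) -> None:
        if self.run_length <= 0 or self.tr <= 0:
            raise ConfigurationError("run_length and tr must be positive")
        total = self.run_length * self.tr
        seen: dict[str, list[tuple[float, float]]] = {}
        for cond, onset, dur in self.events:
            if cond not in self.conditions:
                raise ConfigurationError(f"event condition {cond!r} not declared")
            if onset < 0:
                raise ConfigurationError("event onset must be >= 0")
            if onset + dur > total + 1e-9:
                raise ConfigurationError("event extends past the end of the run")
            seen.setdefault(cond, []).append((onset, onset + dur))
        for cond, spans in seen.items():
            spans.sort()
            for (_, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 < e0 - 1e-9:
                    raise ConfigurationError(f"overlapping events in condition {cond!r}")

    def onsets(self, condition: str) -> list[tuple[float, float]]:
        """(onset, duration) pairs for one condition, in onset order."""
        return sorted(
            (onset, dur) for cond, onset, dur in self.events if cond == condition
        )


@dataclass
class ActivationROI:
    """Spherical activation locus: center voxel, radius (voxels), condition,
    amplitude as % signal change relative to baseline."""

    center: tuple[int, int, int]
    radius: float
    condition: str
    amplitude_pct: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ConfigurationError("ROI radius must be >= 1 voxel")


@dataclass
class PhantomSpec:
    """Everything needed to synthesize one run's clean BOLD series.

    ``drift_amplitude_pct`` / ``drift_period_s`` parameterize a slow sinusoidal
    scanner drift added to every voxel; ``noise_sd_pct`` is white thermal noise,
    both expressed as % of ``baseline``.  ``seed`` fully determines the output.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr: float = 1.0
    n_volumes: int = 192
    activation_rois: list[ActivationROI] = field(default_factory=list)
    baseline: float = 1000.0
    noise_sd_pct: float = 1.0
    noise_smooth_vox: float = 0.75
    drift_amplitude_pct: float = 0.5
    drift_period_s: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_pct < 0 or self.drift_amplitude_pct < 0:
            raise ConfigurationError("noise and drift amplitudes must be >= 0")
        for roi in self.activation_rois:
            for c, n in zip(roi.center, self.shape):
                if not (0 <= c < n):
                    raise ConfigurationError(f"ROI center {roi.center} outside grid {self.shape}")


@dataclass
class MotionTrace:
    """T×6 rigid-body parameters: x, y, z translations (mm) then pitch, yaw,
    roll rotations (radians), relative to the first volume.

    ``spike_frames`` records, for ground-truth traces, the set of frames whose
    frame-to-frame motion is dominated by an injected spike — both the
    displaced frame and the recoil frame following it (a transient spike moves
    the head for one volume and returns, so two successive frame differences
    are large).
    """

    params: np.ndarray
    provenance: str = "ground_truth"
    spike_frames: frozenset[int] = frozenset()
    spike_onsets: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise DataError("motion trace must be T x 6")
        if not np.all(np.isfinite(self.params)):
            raise DataError("motion trace contains non-finite values")
        if self.provenance not in ("ground_truth", "estimated", "file"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class Bold4D:
    """A 4D BOLD series (X×Y×Z×T) with voxel size (mm), TR (s) and an
    optional boolean brain mask on the spatial grid."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr: float = 1.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DataError("BOLD data must be 4D (X, Y, Z, T)")
        if not np.all(np.isfinite(self.data)):
            raise DataError("BOLD data contain non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise DataError("mask shape does not match spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return a (T, n_voxels) matrix of in-mask voxel time series."""
        m = mask if mask is not None else self.mask
        if m is None:
            m = np.ones(self.shape, dtype=bool)
        return self.data[m].T.copy()

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(data=data, voxel_size=self.voxel_size, tr=self.tr, mask=self.mask)


@dataclass
class FDSeries:
    """Framewise displacement per volume (mm); frame 0 is 0 by convention."""

    values: np.ndarray
    rotation_radius: float = 50.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("FD series must be 1-D")
        if np.any(self.values < 0):
            raise DataError("FD values must be >= 0")


@dataclass
class DvarsSeries:
    """DVARS per volume in % ΔBOLD; frame 0 is 0 by convention."""

    values: np.ndarray
    normalization: str = "percent of median in-mask mean intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("DVARS series must be 1-D")
        if np.any(self.values < 0):
            raise DataError("DVARS values must be >= 0")


@dataclass
class OutlierMask:
    """Boolean per-volume motion-outlier flags with detection provenance."""

    flags: np.ndarray
    metric: str
    threshold: float
    units: str = "mm"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise DataError("outlier flags must be 1-D")
        if self.metric not in ("fd", "dvars", "manual"):
            raise ConfigurationError(f"unknown outlier metric {self.metric!r}")

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


@dataclass
class MotionSummary:
    """Per-run motion characterization: the three FD means (mm), spike count,
    and adjusted R² of motion-explained mean-BOLD variance per regressor set."""

    mean_fd: float
    mean_fd_prime: float | None
    mean_fd_doubleprime: float | None
    n_spikes: int
    r2adj: dict[str, float] = field(default_factory=dict)


@dataclass
class DesignMatrix:
    """T×K GLM design with labeled, role-tagged columns.

    Roles are ``task``, ``drift`` and ``intercept``; exactly one intercept
    column is present and task columns are HRF-convolved boxcars.
    """

    matrix: np.ndarray
    labels: list[str]
    roles: list[str]
    tr: float
    hp_cutoff: float | None = None
    hrf_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError("design matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[1] or len(self.roles) != self.matrix.shape[1]:
            raise DataError("labels/roles must match the number of columns")
        if self.roles.count("intercept") != 1:
            raise DataError("design must contain exactly one intercept column")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, label: str) -> int:
        return self.labels.index(label)

    def task_contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Build a length-K contrast vector from {task label: weight}."""
        c = np.zeros(self.n_columns)
        for label, w in weights.items():
            c[self.column_index(label)] = w
        return c


@dataclass
class Cluster:
    """One suprathreshold 26-connected component of a Z map."""

    voxels: np.ndarray  # (n, 3) integer voxel indices
    peak_z: float
    peak_voxel: tuple[int, int, int]
    size: int


@dataclass
class StatMap:
    """Voxelwise Z map for one contrast, with thresholding state."""

    z: np.ndarray
    contrast: np.ndarray
    dof: int
    mask: np.ndarray
    thresholded: bool = False
    voxel_threshold: float | None = None
    clusters: list[Cluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3:
            raise DataError("Z map must be 3-D")

    @property
    def surviving_voxels(self) -> np.ndarray:
        """(n, 3) voxel indices in the union of surviving clusters."""
        if not self.clusters:
            return np.empty((0, 3), dtype=int)
        return np.vstack([c.voxels for c in self.clusters])


@dataclass
class QualityMetrics:
    """Activation-quality metrics of one thresholded map.

    ``z_max``/``z_mean`` are None when no cluster survives thresholding.
    """

    z_max: float | None
    z_mean: float | None
    n_sig_voxels: int
    model_id: str = ""
    run_id: str = ""
    subject_id: str = ""
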