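"""Synthetic task-fMRI phantom: known activation, known motion, known noise.

The phantom emulates the structure of a block-design visual-motion study run
at TR = 1 s: a passive localizer run (192 volumes, 10 blocks of 18 s split
into fixation / static-dots / moving-dots periods) and biological-motion
decision runs (507 volumes, 12 blocks of 40 s drawn from global / local /
scrambled motion conditions).  Activation is placed in a compact spherical
region standing in for the motion-sensitive area hMT+/V5.

Head motion is modeled as a slow random-walk drift plus sporadic transient
spikes: at a spike the head is displaced for exactly one volume and returns
to its drift path, so both the displaced frame and the recoil frame carry a
large frame-to-frame displacement.  The generator records that affected frame
set as ground truth for outlier-detection tests.  Every output is a pure
function of the seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import (
    ActivationROI,
    Bold4D,
    ConfigurationError,
    MotionTrace,
    PhantomSpec,
    TaskDesign,
)
from .hrf import condition_regressor
from .rigid import border_value, resample_rigid

__all__ = [
    "make_task_design",
    "generate_motion_trace",
    "generate_phantom",
    "apply_motion",
    "default_localizer_roi",
]

#: rotations drift with per-step sd = drift_sd / ROTATION_DRIFT_RADIUS so a
#: 50 mm arc matches the translational drift scale (one knob controls FD)
ROTATION_DRIFT_RADIUS = 50.0

# Biological-motion block orders; 12 blocks of 40 s per run, variant "a"
# carries 5 global / 4 local / 3 scrambled blocks and variant "b" 4 / 5 / 3,
# so two runs total 9 global, 9 local, 6 scrambled.
_BM_BLOCKS = {
    "a": ["global", "local", "scrambled", "global", "local", "global",
          "scrambled", "local", "global", "local", "scrambled", "global"],
    "b": ["local", "global", "scrambled", "local", "global", "local",
          "scrambled", "global", "local", "global", "scrambled", "local"],
}


def make_task_design(paradigm: str, tr: float = 1.0) -> TaskDesign:
    """Build one of the study's two block-design presets.

    ``localizer``: 192 volumes, 10 blocks of 18 s (6 s fixation, 6 s static
    dots, 6 s moving dots) after a 12 s lead-in; conditions static / moving.
    ``bm`` (or ``bm_a`` / ``bm_b``): 507 volumes, 12 blocks of 40 s from
    conditions global / local / scrambled, with a 13 s lead-in.
    """
    if paradigm == "localizer":
        events = []
        for k in range(10):
            t0 = 12.0 + 18.0 * k
            events.append(("static", t0 + 6.0, 6.0))
            events.append(("moving", t0 + 12.0, 6.0))
        return TaskDesign(
            conditions=["static", "moving"],
            events=events,
            run_length=int(round(192 / tr)),
            tr=tr,
        )
    if paradigm in ("bm", "bm_a", "bm_b"):
        variant = "b" if paradigm == "bm_b" else "a"
        events = [
            (cond, 13.0 + 40.0 * k, 40.0)
            for k, cond in enumerate(_BM_BLOCKS[variant])
        ]
        return TaskDesign(
            conditions=["global", "local", "scrambled"],
            events=events,
            run_length=int(round(507 / tr)),
            tr=tr,
        )
    raise ConfigurationError(
        f"unknown paradigm {paradigm!r}; expected 'localizer', 'bm', 'bm_a' or 'bm_b'"
    )


def generate_motion_trace(
    n_volumes: int,
    drift_sd: float = 0.02,
    n_spikes: int = 3,
    spike_amplitude: float = 1.0,
    seed: int = 0,
) -> MotionTrace:
    """Random-walk drift plus isolated transient spikes.

    Translations follow independent random walks with per-step sd ``drift_sd``
    mm; rotations with sd ``drift_sd / 50`` rad so their 50 mm-arc equivalent
    matches.  Each spike displaces a single volume (drawn uniformly from
    1..T-1, never volume 0, spikes separated by >= 2 frames) along a random
    direction whose FD magnitude (L1 translations + 50 mm-arc rotations)
    equals ``spike_amplitude``, then returns to the drift path.
    """
    if drift_sd < 0 or spike_amplitude < 0:
        raise ConfigurationError("drift_sd and spike_amplitude must be >= 0")
    if n_spikes < 0 or n_spikes >= n_volumes:
        raise ConfigurationError("need 0 <= n_spikes < n_volumes")
    rng = np.random.default_rng(seed)

    params = np.zeros((n_volumes, 6))
    if n_volumes > 1:
        steps = rng.normal(0.0, 1.0, size=(n_volumes - 1, 6))
        steps[:, :3] *= drift_sd
        steps[:, 3:] *= drift_sd / ROTATION_DRIFT_RADIUS
        params[1:] = np.cumsum(steps, axis=0)

    onsets: list[int] = []
    if n_spikes:
        if n_spikes > (n_volumes - 1) // 2:
            raise ConfigurationError("too many spikes for the run length")
        while len(onsets) < n_spikes:
            cand = int(rng.integers(1, n_volumes))
            if all(abs(cand - s) >= 2 for s in onsets):
                onsets.append(cand)
        onsets.sort()
    affected: set[int] = set()
    for s in onsets:
        direction = rng.normal(size=6)
        weights = np.array([1.0] * 3 + [ROTATION_DRIFT_RADIUS] * 3)
        direction *= spike_amplitude / np.sum(np.abs(direction) * weights)
        params[s] += direction
        affected.add(s)
        if s + 1 < n_volumes:
            affected.add(s + 1)

    return MotionTrace(
        params=params,
        provenance="ground_truth",
        spike_frames=frozenset(affected),
        spike_onsets=frozenset(onsets),
    )


def default_localizer_roi(shape: tuple[int, int, int], condition: str = "moving",
                          amplitude_pct: float = 2.0) -> ActivationROI:
    """A compact lateral-posterior sphere standing in for hMT+/V5."""
    center = (int(shape[0] * 0.7), int(shape[1] * 0.35), int(shape[2] * 0.45))
    return ActivationROI(center=center, radius=max(2.0, min(shape) / 8.0),
                         condition=condition, amplitude_pct=amplitude_pct)


def _baseline_volume(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth ellipsoidal 'brain' with mild random texture; background ~ 0.

    The three semi-axes are distinct (head-like anisotropy), which also makes
    rotations identifiable to intensity-based realignment.
    """
    shape = np.array(spec.shape, dtype=float)
    grids = np.meshgrid(*[np.arange(n) for n in spec.shape], indexing="ij")
    center = (shape - 1) / 2.0
    radii = shape * np.array([0.40, 0.34, 0.29])
    rho = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)))
    profile = 1.0 / (1.0 + np.exp((rho - 1.0) * 10.0))
    texture = ndimage.gaussian_filter(rng.normal(size=spec.shape), sigma=1.5)
    texture /= max(np.abs(texture).max(), 1e-12)
    return spec.baseline * profile * (1.0 + 0.10 * texture)


def generate_phantom(
    spec: PhantomSpec, design: TaskDesign
) -> tuple[Bold4D, dict[str, np.ndarray]]:
    """Synthesize a clean (motion-free) run plus its ground-truth activation.

    Voxel time series::

        baseline(x) * (1 + sum_roi amplitude * regressor(t) + drift(t)) + noise

    where ``regressor`` is the HRF-convolved boxcar of the ROI's condition
    normalized to peak 1 (so ``amplitude`` is peak % signal change), ``drift``
    a slow sinusoid, and ``noise`` white Gaussian.  Returns the Bold4D (with
    its brain mask) and, per condition, the true peak %-signal-change map.
    """
    if design.run_length != spec.n_volumes:
        raise ConfigurationError(
            f"design length {design.run_length} != spec.n_volumes {spec.n_volumes}"
        )
    rng = np.random.default_rng(spec.seed)
    base = _baseline_volume(spec, rng)
    mask = base > 0.5 * spec.baseline

    t_idx = np.arange(spec.n_volumes)
    data = np.repeat(base[..., np.newaxis], spec.n_volumes, axis=3)

    truth: dict[str, np.ndarray] = {c: np.zeros(spec.shape) for c in design.conditions}
    grids = np.meshgrid(*[np.arange(n) for n in spec.shape], indexing="ij")
    for roi in spec.activation_rois:
        if roi.condition not in design.conditions:
            raise ConfigurationError(f"ROI condition {roi.condition!r} not in design")
        reg = condition_regressor(design, roi.condition)
        peak = reg.max()
        if peak > 0:
            reg = reg / peak
        dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, roi.center)))
        roi_mask = dist <= roi.radius
        if not roi_mask.any():
            raise ConfigurationError("ROI sphere contains no voxels")
        amp = roi.amplitude_pct / 100.0
        data[roi_mask] += np.outer(base[roi_mask] * amp, reg)
        truth[roi.condition][roi_mask] += roi.amplitude_pct

    if spec.drift_amplitude_pct > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = np.sin(2 * np.pi * t_idx * spec.tr / spec.drift_period_s + phase)
        data += (spec.drift_amplitude_pct / 100.0) * base[..., np.newaxis] * drift

    if spec.noise_sd_pct > 0:
        sd = spec.baseline * spec.noise_sd_pct / 100.0
        noise = rng.normal(0.0, 1.0, size=data.shape)
        if spec.noise_smooth_vox > 0:
            # real EPI thermal noise is spatially correlated; smoothing (and
            # rescaling back to unit sd) prevents resampling from modulating
            # the noise variance in an unphysical frame-position-dependent way
            s = spec.noise_smooth_vox
            noise = ndimage.gaussian_filter(noise, sigma=(s, s, s, 0.0))
            noise /= noise.std()
        data += sd * noise

    bold = Bold4D(data=data, voxel_size=spec.voxel_size, tr=spec.tr, mask=mask)
    return bold, truth


def apply_motion(
    clean: Bold4D, trace: MotionTrace, spike_intensity_pct: float = 0.0
) -> Bold4D:
    """Forward motion model: resample each volume under its rigid transform.

    Trilinear interpolation, edges padded with the phantom's own background
    level.  At spike-displaced volumes an additional global intensity scaling
    of ``spike_intensity_pct`` percent emulates the spin-history/intensity
    artifact that accompanies abrupt motion, giving image-based (DVARS)
    detection a target.
    """
    if trace.n_volumes != clean.n_volumes:
        raise ConfigurationError("motion trace length does not match BOLD series")
    pad = border_value(clean.data[..., 0])
    out = np.empty_like(clean.data)
    for t in range(clean.n_volumes):
        p = trace.params[t]
        if np.any(p != 0):
            out[..., t] = resample_rigid(clean.data[..., t], p, clean.voxel_size,
                                         pad_value=pad)
        else:
            out[..., t] = clean.data[..., t]
        if spike_intensity_pct != 0.0 and t in trace.spike_onsets:
            out[..., t] *= 1.0 + spike_intensity_pct / 100.0
    return clean.with_data(out)
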