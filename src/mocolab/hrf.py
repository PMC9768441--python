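"""Canonical double-gamma hemodynamic response function and boxcar convolution."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import TaskDesign

__all__ = ["canonical_hrf", "condition_regressor", "HRF_PARAMS"]

# Canonical double-gamma parameterization: response peak 6 s, undershoot peak
# 16 s, unit dispersions, undershoot weighted 1/6, 32 s support.
HRF_PARAMS = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
    "length": 32.0,
}


def canonical_hrf(tr: float, oversampling: int = 1) -> np.ndarray:
    """Sample the canonical double-gamma HRF at ``tr`` seconds, peak scaled to 1.

    The kernel is the difference of two gamma densities (shape = delay /
    dispersion, scale = dispersion), evaluated on [0, 32 s).  With shape > 1
    the density is 0 at t = 0, so the kernel starts at zero.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    p = HRF_PARAMS
    dt = tr / oversampling
    t = np.arange(0, p["length"], dt)
    peak = stats.gamma.pdf(t, a=p["peak_delay"] / p["peak_dispersion"], scale=p["peak_dispersion"])
    under = stats.gamma.pdf(
        t, a=p["undershoot_delay"] / p["undershoot_dispersion"], scale=p["undershoot_dispersion"]
    )
    h = peak - p["undershoot_ratio"] * under
    return h / h.max()


def condition_regressor(design: TaskDesign, condition: str, oversampling: int = 16) -> np.ndarray:
    """HRF-convolved unit boxcar for one condition, sampled at volume times.

    The boxcar (1 during the condition's events, 0 elsewhere) is built on a
    grid ``oversampling`` times finer than the TR, convolved with the HRF on
    that grid, then decimated to the T volume acquisition times.
    """
    tr = design.tr
    n = design.run_length
    dt = tr / oversampling
    fine = np.zeros(n * oversampling)
    tgrid = np.arange(fine.size) * dt
    for onset, dur in design.onsets(condition):
        fine[(tgrid >= onset) & (tgrid < onset + dur)] = 1.0
    if not fine.any():
        return np.zeros(n)
    kernel = canonical_hrf(tr, oversampling=oversampling)
    # dt factor approximates the continuous convolution integral, so the
    # regressor scale is independent of the oversampling rate
    conv = np.convolve(fine, kernel)[: fine.size] * dt
    return conv[::oversampling].copy()
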