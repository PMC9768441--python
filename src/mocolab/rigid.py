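"""Rigid-body geometry: rotation matrices and trilinear resampling.

The head position at volume *i* is modeled as a rigid map in scanner mm
coordinates::

    A(x) = R (x - c) + c + t

with ``t`` the translations (mm), ``R`` the rotation built from intrinsic
pitch-yaw-roll angles about axes through the volume center ``c``, applied in
the order ``R = Rz(roll) @ Ry(yaw) @ Rx(pitch)``.  Moving the head by
parameters ``p`` turns a clean volume ``I`` into ``I'(x) = I(A⁻¹ x)``;
realignment resamples with ``A`` itself (``invert=True``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["rotation_matrix", "resample_rigid", "border_value"]


def rotation_matrix(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Intrinsic pitch (x), yaw (y), roll (z) rotation, composed Rz @ Ry @ Rx."""
    ca, sa = np.cos(pitch), np.sin(pitch)
    cb, sb = np.cos(yaw), np.sin(yaw)
    cg, sg = np.cos(roll), np.sin(roll)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz @ ry @ rx


def border_value(volume: np.ndarray) -> float:
    """Median intensity of the volume's outer faces — the background level
    used to pad during resampling so edges do not invent intensity steps."""
    faces = [
        volume[0], volume[-1],
        volume[:, 0], volume[:, -1],
        volume[:, :, 0], volume[:, :, -1],
    ]
    return float(np.median(np.concatenate([f.ravel() for f in faces])))


def resample_rigid(
    volume: np.ndarray,
    params: np.ndarray,
    voxel_size: tuple[float, float, float],
    invert: bool = False,
    pad_value: float | None = None,
    order: int = 1,
) -> np.ndarray:
    """Resample a 3D volume under the rigid map for ``params`` (6-vector).

    ``invert=False`` renders the volume as seen after the head moved by
    ``params`` (forward model); ``invert=True`` undoes that motion
    (realignment).  Trilinear interpolation by default, constant padding with
    the volume's own background level unless ``pad_value`` is given.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError("rigid parameters must be a 6-vector")
    t = params[:3]
    r = rotation_matrix(*params[3:])
    v = np.asarray(voxel_size, dtype=float)
    center = (np.array(volume.shape) - 1) / 2.0 * v

    if invert:
        # output voxel i samples input at V⁻¹ [R(Vi − c) + c + t]
        m = r
        off = t + center - r @ center
    else:
        rinv = r.T
        m = rinv
        off = center - rinv @ (center + t)

    matrix = m * (v[np.newaxis, :] / v[:, np.newaxis])  # V⁻¹ M V
    offset = off / v
    if pad_value is None:
        pad_value = border_value(volume)
    return ndimage.affine_transform(
        volume, matrix, offset=offset, order=order, mode="constant", cval=pad_value
    )
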