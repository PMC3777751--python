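"""Rigid-body (6-parameter) volume transforms.

Shared by the phantom's motion injection and the motion-correction estimator
so that the two use one convention: parameters are
(tx, ty, tz) translations in mm and (rx, ry, rz) rotations in degrees,
rotations applied about the volume center in the order Rz @ Ry @ Rx.
``apply_rigid(vol, p)`` moves the image *content* by +t after rotating it,
i.e. a head that translated by +2 mm in x produces a volume equal to
``apply_rigid(reference, (2, 0, 0, 0, 0, 0))``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid(
    vol: np.ndarray,
    params: np.ndarray,
    voxel_size: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Resample ``vol`` under the rigid motion ``params``.

    World coordinates are mm relative to the volume center; a point at x
    moves to y = R x + t.  The resampling therefore pulls each output voxel
    from x = R^-1 (y - t), with trilinear interpolation by default and
    zero-filled out-of-field voxels.
    """
    params = np.asarray(params, dtype=np.float64)
    if np.allclose(params, 0):
        return vol.copy()
    t = params[:3]
    R = rotation_matrix(*params[3:6])
    S = np.diag(np.asarray(voxel_size, dtype=np.float64))
    S_inv = np.diag(1.0 / np.asarray(voxel_size, dtype=np.float64))
    Rinv = R.T
    M = S_inv @ Rinv @ S
    center = (np.asarray(vol.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - M @ center - S_inv @ Rinv @ t
    return ndimage.affine_transform(
        vol, M, offset=offset, order=order, mode="constant", cval=0.0
    )
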