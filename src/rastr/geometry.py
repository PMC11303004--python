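"""Shared geometric conventions.

All 2D images are indexed ``img[y, x]`` (row, column) with the image center
at ``((n-1)/2, (n-1)/2)`` in 0-based pixel coordinates.  Angles are in
degrees throughout.

The in-plane angle ``psi`` of a tube is the angle between the tube axis and
the image y (vertical) axis, measured so that the axis direction vector is
``(sin psi, cos psi)`` in (x, y).  ``rotate_image(img, -psi)`` therefore
brings the tube axis vertical, and ``rotate_image(img, delta)`` changes the
apparent psi of any feature by ``+delta``.

3D volumes are indexed ``vol[z, y, x]`` with the tube axis along z.  Euler
angles follow the ZYZ convention: ``phi`` about z (azimuth around the tube),
``theta`` about y (tube polarity; 90 or 270), ``psi`` in-plane.  The
projection orientation matrix carries a fixed internal 90-degree offset so
that at ``theta=90, psi=0`` the tube axis projects onto the image y axis,
consistent with the 2D convention above.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "image_center",
    "rotate_image",
    "shift_image",
    "rot2",
    "euler_matrix",
]


def image_center(n: int) -> float:
    """Center coordinate of an n-pixel axis (0-based)."""
    return (n - 1) / 2.0


def rotate_image(img: np.ndarray, angle_deg: float, order: int = 3) -> np.ndarray:
    """Rotate image content by ``angle_deg`` about the image center.

    A tube at in-plane angle psi appears at ``psi + angle_deg`` afterwards.
    """
    if angle_deg == 0:
        return img.astype(np.float64, copy=True)
    return ndimage.rotate(
        img.astype(np.float64), angle_deg, reshape=False, order=order,
        mode="constant", cval=0.0,
    )


def shift_image(img: np.ndarray, dx: float, dy: float, order: int = 3) -> np.ndarray:
    """Translate image content by (+dx, +dy) pixels in (x, y)."""
    if dx == 0 and dy == 0:
        return img.astype(np.float64, copy=True)
    return ndimage.shift(
        img.astype(np.float64), (dy, dx), order=order, mode="constant", cval=0.0,
    )


def rot2(angle_deg: float) -> np.ndarray:
    """2x2 matrix acting on (x, y) content positions under rotate_image."""
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])


def _rz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_matrix(phi_deg: float, theta_deg: float, psi_deg: float) -> np.ndarray:
    """Volume-to-lab rotation matrix for ZYZ Euler angles.

    Maps volume (x, y, z) coordinates into the lab frame whose x/y axes are
    the image axes and whose z axis is the projection (viewing) direction.
    Includes the fixed 90-degree in-plane offset that places the tube axis
    (volume z) along image y at ``theta=90, psi=0``; the sign of psi matches
    :func:`rotate_image` (a tube projected at psi appears at in-plane angle
    psi under the 2D convention above).
    """
    return _rz(90.0 - psi_deg) @ _ry(theta_deg) @ _rz(phi_deg)
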