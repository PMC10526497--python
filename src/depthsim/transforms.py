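"""Homogeneous-coordinate geometry for a planar binocular world.

Points live in the projective plane as length-3 vectors ``(x, y, w)``; the
world's depth axis is ``x`` and the lateral axis is ``y``.  Affine maps keep
the last row of the 3x3 transform at ``(0, 0, 1)`` so that points stay on the
``w = 1`` plane, while perspective maps deliberately break that row and
require re-normalisation.

Every forward map here is paired with an analytic adjoint (``backprop_*``)
that contracts a downstream error vector with the map's Jacobian; these are
the only derivatives the inference machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegeneratePointError(ValueError):
    """Raised when a projective operation hits a point it cannot handle
    (point at infinity, or zero depth at a camera)."""


@dataclass(frozen=True)
class Camera:
    """Pinhole camera with focal length ``f`` (distance of the image plane
    from the eye's origin, in world length units)."""

    f: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"focal length must be positive, got {self.f}")


def homogeneous_point(x: float, y: float, w: float = 1.0) -> np.ndarray:
    """Build a homogeneous 2D point ``(x, y, w)`` as a float array."""
    return np.array([x, y, w], dtype=float)


def normalize_homogeneous(p: np.ndarray) -> np.ndarray:
    """Scale ``p`` so its projective coordinate equals 1.

    Raises
    ------
    DegeneratePointError
        If ``p[2] == 0`` (point at infinity).
    """
    p = np.asarray(p, dtype=float)
    if p[2] == 0.0:
        raise DegeneratePointError("cannot normalize a point at infinity (w = 0)")
    return p / p[2]


def make_rototranslation(theta: float, lx: float, ly: float) -> np.ndarray:
    """Rotation by ``theta`` composed after translation by ``(lx, ly)``.

    Applied to ``(px, py, 1)`` this yields
    ``(c(px+lx) - s(py+ly), s(px+lx) + c(py+ly), 1)`` with ``c, s`` the
    cosine and sine of ``theta``.
    """
    c, s = np.cos(theta), np.sin(theta)
    rotation = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    translation = np.array([[1.0, 0.0, lx], [0.0, 1.0, ly], [0.0, 0.0, 1.0]])
    return rotation @ translation


def make_perspective(zx: float, zy: float) -> np.ndarray:
    """Perspective transform: maps ``(x, y, 1)`` to ``(x, y, zx*x + zy*y + 1)``."""
    return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [zx, zy, 1.0]])


def make_eye_transform(theta_abs: float, l: float) -> np.ndarray:
    """Extrinsic world-to-eye transform for an eye at lateral offset ``l``
    rotated by the absolute angle ``theta_abs``.

    The matrix is ``[[c, s, -l*s], [-s, c, -l*c], [0, 0, 1]]``; its rotation
    block is the inverse (transpose) of a world rotation by ``theta_abs``, so
    a point straight ahead of the eye maps onto the eye's depth axis.
    """
    c, s = np.cos(theta_abs), np.sin(theta_abs)
    return np.array([[c, s, -l * s], [-s, c, -l * c], [0.0, 0.0, 1.0]])


def d_eye_transform_dtheta(theta_abs: float, l: float) -> np.ndarray:
    """Entry-wise derivative of :func:`make_eye_transform` w.r.t. the angle."""
    c, s = np.cos(theta_abs), np.sin(theta_abs)
    return np.array([[-s, c, -l * c], [-c, -s, l * s], [0.0, 0.0, 0.0]])


def apply_transform(T: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Matrix-apply ``T`` to the homogeneous point ``p`` (no normalisation)."""
    return np.asarray(T, dtype=float) @ np.asarray(p, dtype=float)


def project_to_camera(r: np.ndarray, cam: Camera) -> np.ndarray:
    """Project an eye-frame point onto the camera plane.

    ``r`` must be normalised (``w = 1``) with nonzero depth ``r[0]``; the
    image point is returned homogeneously as ``(1, f * r_y / r_x)`` so the
    plane's centre is ``(1, 0)``.
    """
    r = np.asarray(r, dtype=float)
    if r[0] == 0.0:
        raise DegeneratePointError("point has zero depth in the eye frame")
    return np.array([1.0, cam.f * r[1] / r[0]])


def backprop_point(T: np.ndarray, err: np.ndarray) -> np.ndarray:
    """Pull a 3-vector error back through ``apply_transform``: returns ``T.T @ err``."""
    return np.asarray(T, dtype=float).T @ np.asarray(err, dtype=float)


def backprop_param(dT_dparam: np.ndarray, err: np.ndarray, mu_r: np.ndarray) -> float:
    """Gradient of ``err . (T(param) @ mu_r)`` w.r.t. a scalar transform parameter.

    Computed as the total contraction of the entry-wise derivative matrix
    with the outer product ``err mu_r^T``.
    """
    return float(np.sum(np.asarray(dT_dparam) * np.outer(err, mu_r)))


def backprop_projection(r: np.ndarray, cam: Camera, err: float) -> np.ndarray:
    """Gradient of the image coordinate ``f * r_y / r_x`` w.r.t. ``(r_x, r_y)``,
    contracted with a scalar error: ``(-f*r_y/r_x**2 * err, f/r_x * err)``."""
    r = np.asarray(r, dtype=float)
    if r[0] == 0.0:
        raise DegeneratePointError("point has zero depth in the eye frame")
    return np.array([-cam.f * r[1] / r[0] ** 2 * err, cam.f / r[0] * err])


def triangulate_parallel(c0: float, c1: float, cam: Camera, half_distance: float) -> np.ndarray:
    """Closed-form two-ray intersection for parallel, unrotated eyes.

    Eyes sit at lateral offsets ``+half_distance`` (index 0) and
    ``-half_distance`` (index 1); with image coordinates
    ``c_i = f * (y - l_i) / x`` the disparity gives
    ``x = 2 f L / (c1 - c0)`` and ``y`` follows by back-substitution.
    """
    disparity = c1 - c0
    if disparity == 0.0:
        raise DegeneratePointError("zero disparity: rays are parallel")
    x = 2.0 * cam.f * half_distance / disparity
    y = x * (c0 + c1) / (2.0 * cam.f)
    return np.array([x, y])
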