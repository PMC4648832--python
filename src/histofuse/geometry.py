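"""Rigid-body geometry primitives in millimetre world coordinates.

Conventions
-----------
World coordinates are right-handed, in mm.  The ``z`` axis is the specimen
cutting axis, i.e. perpendicular to the nominal histology planes; an axial
candidate plane is ``z = const``.  Transforms are stored as a proper rotation
matrix plus a translation vector and serialize as a 4x4 homogeneous matrix
(row major).  Histology pixel coordinates (micrometres, row increasing
downward) are converted to mm with ``y`` increasing upward at the I/O
boundary only -- everything in this module is already metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateConfigurationError",
    "RigidTransform3D",
    "RigidTransform2D",
    "LineFiducial",
    "PointFiducial",
    "compose",
    "invert",
    "transform_points",
    "intersect_line_with_plane",
]

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input (non-rigid matrix, empty point set, ...)."""


class DegenerateConfigurationError(GeometryError):
    """A configuration with no unique answer (e.g. a line lying in the plane)."""


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if R.shape != (3, 3):
        raise GeometryError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise GeometryError("rotation matrix contains non-finite entries")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > tol * 10:  # allow a little accumulated round-off
        raise GeometryError(f"matrix is not orthonormal (max |R'R - I| = {err:g})")
    det = np.linalg.det(R)
    if abs(det - 1.0) > 1e-6:
        raise GeometryError(f"matrix is not a proper rotation (det = {det:g})")


@dataclass(frozen=True)
class RigidTransform3D:
    """A proper rigid motion ``p -> R p + t`` of 3-space (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(R)
        if not np.all(np.isfinite(t)):
            raise GeometryError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform3D":
        """Build from a 4x4 homogeneous matrix."""
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise GeometryError(f"homogeneous matrix must be 4x4, got {M.shape}")
        if not np.allclose(M[3], [0, 0, 0, 1], atol=1e-9):
            raise GeometryError("last row of homogeneous matrix must be [0,0,0,1]")
        return cls(M[:3, :3], M[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single (3,) point)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out


@dataclass(frozen=True)
class RigidTransform2D:
    """An in-plane rigid motion: rotation by ``theta`` (optionally preceded by
    a mirror about the x axis when ``reflected``) followed by a translation.

    The reflection flag exists because a histology section can be mounted on
    the slide face-down; it is never engaged unless the caller asks for it.
    """

    theta: float
    translation: np.ndarray
    reflected: bool = False

    def __post_init__(self) -> None:
        th = float(self.theta)
        # normalize to (-pi, pi]
        th = th - 2 * np.pi * np.floor((th + np.pi) / (2 * np.pi))
        if th <= -np.pi:
            th += 2 * np.pi
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if not (np.isfinite(th) and np.all(np.isfinite(t))):
            raise GeometryError("non-finite 2-D transform parameters")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, np.zeros(2))

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part (rotation, times a mirror if reflected)."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        if self.reflected:
            R = R @ np.diag([1.0, -1.0])
        return R

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform2D":
        Rinv = self.matrix.T  # orthogonal (works for the reflected case too)
        tinv = -Rinv @ self.translation
        if not self.reflected:
            return RigidTransform2D(-self.theta, tinv)
        # Rinv = F R(-theta); express as R(phi) F with phi = atan2 terms
        phi = float(np.arctan2(Rinv[1, 0], Rinv[0, 0]))
        return RigidTransform2D(phi, tinv, reflected=True)


@dataclass(frozen=True)
class LineFiducial:
    """A needle-implanted spine idealized as a 3-D line segment.

    ``origin`` is one end of the segment, ``direction`` the unit vector toward
    the other end, ``length`` the segment length in mm.  The 0.5 mm physical
    diameter of the spines is ignored.
    """

    label: str
    origin: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.all(np.isfinite(o)):
            raise GeometryError(f"fiducial {self.label!r}: non-finite origin")
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise GeometryError(f"fiducial {self.label!r}: zero direction")
            d = d / n
        if not (self.length > 0):
            raise GeometryError(f"fiducial {self.label!r}: length must be > 0")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "length", float(self.length))

    @property
    def end(self) -> np.ndarray:
        return self.origin + self.length * self.direction

    def z_extent(self) -> tuple[float, float]:
        z0, z1 = self.origin[2], self.end[2]
        return (min(z0, z1), max(z0, z1))


@dataclass(frozen=True)
class PointFiducial:
    """An anatomical landmark usable in the in-plane search.

    Unlike a spine it has no axial extent: it contributes an in-plane point
    only for candidate planes within ``z_tolerance`` of its own z (landmarks
    are typically confined to one or two consecutive axial slices).
    """

    label: str
    position: np.ndarray
    z_tolerance: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise GeometryError(f"landmark {self.label!r}: non-finite position")
        if self.z_tolerance < 0:
            raise GeometryError("z_tolerance must be >= 0")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "z_tolerance", float(self.z_tolerance))


def compose(first: RigidTransform3D, second: RigidTransform3D) -> RigidTransform3D:
    """The transform equivalent to applying ``first`` then ``second``."""
    R = second.rotation @ first.rotation
    t = second.rotation @ first.translation + second.translation
    # re-orthonormalize to keep long chains within tolerance
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    return RigidTransform3D(R, t)


def invert(T: RigidTransform3D) -> RigidTransform3D:
    """The inverse motion: ``compose(T, invert(T))`` is the identity."""
    Rinv = T.rotation.T
    return RigidTransform3D(Rinv, -Rinv @ T.translation)


def transform_points(T: RigidTransform3D, points: np.ndarray) -> np.ndarray:
    """Apply ``T`` to an (N, 3) array of points; N must be >= 1."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise GeometryError("transform_points requires a nonempty point set")
    if pts.shape[1] != 3:
        raise GeometryError(f"expected (N, 3) points, got {pts.shape}")
    return T.apply(pts)


def intersect_line_with_plane(f: LineFiducial, z_plane: float) -> np.ndarray | None:
    """In-plane (x, y) where the segment crosses the axial plane ``z = z_plane``.

    Returns ``None`` when the segment does not reach the plane or is parallel
    to it; raises :class:`DegenerateConfigurationError` when the segment lies
    exactly in the plane (every point intersects -- no unique answer).
    """
    dz = f.direction[2]
    if abs(dz) < 1e-12:
        if abs(f.origin[2] - z_plane) < 1e-12:
            raise DegenerateConfigurationError(
                f"fiducial {f.label!r} lies in the plane z={z_plane}"
            )
        return None
    s = (z_plane - f.origin[2]) / dz
    if s < 0.0 or s > f.length:
        return None
    p = f.origin + s * f.direction
    return p[:2].copy()
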