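"""Least-squares point-based rigid registration (3-D and 2-D).

Both fits solve the orthogonal Procrustes problem without scaling in closed
form: subtract centroids, SVD the cross-covariance, and correct the
determinant sign so that only proper rotations are returned (the Kabsch /
Horn solution).  This is the exact global optimum -- there is no iterative
tolerance to tune.  Reflections are excluded unless explicitly allowed in
2-D, where a section mounted face-down on the slide is a physical
possibility.

Correspondence between points is given by labels: landmark identification is
manual, no automatic matching is attempted, and all landmarks are weighted
equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DegenerateConfigurationError,
    GeometryError,
    RigidTransform2D,
    RigidTransform3D,
)

__all__ = [
    "InsufficientLandmarksError",
    "Correspondences3D",
    "Correspondences2D",
    "FitResult",
    "fit_rigid_3d",
    "fit_rigid_2d",
    "rms_residual",
]

MIN_PAIRS = 3  # a rigid fit in either dimension needs at least three landmarks


class InsufficientLandmarksError(ValueError):
    """Fewer landmark pairs than the fit requires."""


def _validate_pairs(labels, source, target, dim: int):
    labels = list(labels)
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape[1] != dim or tgt.shape != src.shape:
        raise GeometryError(
            f"expected matching (N, {dim}) source/target arrays, "
            f"got {src.shape} and {tgt.shape}"
        )
    if len(labels) != src.shape[0]:
        raise GeometryError("one label per correspondence pair is required")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise GeometryError(f"duplicate correspondence labels: {dupes}")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise GeometryError("correspondences contain non-finite coordinates")
    return labels, src, tgt


@dataclass(frozen=True)
class Correspondences3D:
    """Labeled 3-D landmark pairs (source -> target), mm."""

    labels: list
    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        labels, src, tgt = _validate_pairs(self.labels, self.source, self.target, 3)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    def __len__(self) -> int:
        return len(self.labels)

    def drop(self, label) -> "Correspondences3D":
        """A copy with one labeled pair removed (for leave-one-out)."""
        if label not in self.labels:
            raise KeyError(label)
        keep = [i for i, l in enumerate(self.labels) if l != label]
        return Correspondences3D(
            [self.labels[i] for i in keep], self.source[keep], self.target[keep]
        )


@dataclass(frozen=True)
class Correspondences2D:
    """Labeled in-plane point pairs (source -> target), mm."""

    labels: list
    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        labels, src, tgt = _validate_pairs(self.labels, self.source, self.target, 2)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class FitResult:
    """A fitted transform with its residual diagnostics.

    ``rms`` is the fiducial registration error (FRE): the root-mean-square
    post-transform source-to-target distance.  ``per_point_residuals`` are
    the individual distances in the same order as the correspondence labels.
    """

    transform: object  # RigidTransform3D | RigidTransform2D
    rms: float
    per_point_residuals: np.ndarray


def _check_fittable(src: np.ndarray, what: str) -> None:
    if src.shape[0] < MIN_PAIRS:
        raise InsufficientLandmarksError(
            f"{what} needs at least {MIN_PAIRS} pairs, got {src.shape[0]}"
        )
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-6:  # second principal extent ~ 0 => (near-)collinear
        raise DegenerateConfigurationError(
            f"{what}: source points are collinear (second principal extent "
            f"{svals[1]:.2e} mm); the rotation is not identifiable"
        )


def _residuals(moved: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    d = np.linalg.norm(moved - target, axis=1)
    return float(np.sqrt(np.mean(d**2))), d


def fit_rigid_3d(c: Correspondences3D) -> FitResult:
    """Least-squares proper rigid transform taking ``c.source`` onto ``c.target``."""
    _check_fittable(c.source, "3-D rigid fit")
    sc, tc = c.source.mean(axis=0), c.target.mean(axis=0)
    H = (c.source - sc).T @ (c.target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    T = RigidTransform3D(R, t)
    rms, res = _residuals(T.apply(c.source), c.target)
    return FitResult(T, rms, res)


def _fit_2d_proper(src: np.ndarray, tgt: np.ndarray) -> RigidTransform2D:
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    # optimal proper rotation angle in closed form
    theta = float(np.arctan2(H[0, 1] - H[1, 0], H[0, 0] + H[1, 1]))
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return RigidTransform2D(theta, tc - R @ sc)


def fit_rigid_2d(c: Correspondences2D, allow_reflection: bool = False) -> FitResult:
    """Least-squares in-plane rigid transform; optionally consider a mirrored fit.

    With ``allow_reflection`` the better of the proper and the reflected
    solution is returned, with ``transform.reflected`` set accordingly.
    """
    _check_fittable(c.source, "2-D rigid fit")
    T = _fit_2d_proper(c.source, c.target)
    rms, res = _residuals(T.apply(c.source), c.target)
    if allow_reflection:
        mirrored = c.source * np.array([1.0, -1.0])
        Tm = _fit_2d_proper(mirrored, c.target)
        Tr = RigidTransform2D(Tm.theta, Tm.translation, reflected=True)
        rms_r, res_r = _residuals(Tr.apply(c.source), c.target)
        if rms_r < rms:
            return FitResult(Tr, rms_r, res_r)
    return FitResult(T, rms, res)


def rms_residual(T, c) -> float:
    """RMS source-to-target distance after applying ``T`` (any transform)."""
    if len(c) == 0:
        raise GeometryError("rms_residual requires at least one pair")
    rms, _ = _residuals(T.apply(c.source), c.target)
    return rms
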