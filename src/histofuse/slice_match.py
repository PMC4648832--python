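"""Finding the ex vivo CT plane that corresponds to a histology slice.

Line fiducials (implanted spines) cross many axial planes.  For a fixed
histology slice we register its in-plane marker pattern to the fiducial
cross-sections of every candidate CT plane and record the residual RMS
inter-marker distance.  Because the spines are mutually non-parallel
(inserted at roughly 30 degrees to each other), the cross-section pattern
changes shape along z and the RMS curve dips sharply at the true cutting
plane.  A negative Gaussian dip

    rms(z) ~ a - b * exp(-(z - mu)**2 / c**2)

is fitted to the curve and its centre ``mu`` gives a sub-slice estimate of
the corresponding plane; if the fit fails the discrete argmin of the curve
is used instead.

Anatomical landmarks can join the search as point fiducials: they contribute
an in-plane point only for planes within half a slice spacing of their own
z, so they sharpen the dip near the true plane and drop out elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import LineFiducial, PointFiducial, intersect_line_with_plane
from .registration import (
    MIN_PAIRS,
    Correspondences2D,
    FitResult,
    InsufficientLandmarksError,
    fit_rigid_2d,
)

__all__ = [
    "RmsCurve",
    "GaussianFit",
    "SliceMatch",
    "in_plane_fiducials_at_z",
    "rms_curve",
    "fit_negative_gaussian",
    "find_corresponding_plane",
]


@dataclass(frozen=True)
class RmsCurve:
    """Residual in-plane RMS distance as a function of candidate plane z (mm)."""

    z_values: np.ndarray
    rms_values: np.ndarray
    n_points_used: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        r = np.asarray(self.rms_values, dtype=float)
        n = np.asarray(self.n_points_used, dtype=int)
        if z.ndim != 1 or z.shape != r.shape or z.shape != n.shape:
            raise ValueError("z, rms and n arrays must be 1-D and equal length")
        if z.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z values must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rms values must be >= 0")
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "rms_values", r)
        object.__setattr__(self, "n_points_used", n)

    def __len__(self) -> int:
        return self.z_values.size

    @property
    def grid_spacing(self) -> float:
        if len(self) < 2:
            return 1.0
        return float(np.min(np.diff(self.z_values)))


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of the fitted dip ``a - b*exp(-(z-mu)^2/c^2)``.

    ``a`` is the far-field RMS level, ``b`` the dip depth, ``c`` the dip
    width and ``mu`` the dip centre (all in the units of the curve).  The
    fitted minimum value ``a - b`` may undershoot zero; consumers clamp it.
    """

    a: float
    b: float
    c: float
    mu: float
    converged: bool

    @property
    def rms_at_min(self) -> float:
        return self.a - self.b

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.a - self.b * np.exp(-((z - self.mu) ** 2) / self.c**2)


@dataclass(frozen=True)
class SliceMatch:
    """The matched plane for one histology slice."""

    z_star: float
    rms_star: float
    method: str  # "gaussian" | "discrete_argmin"
    curve: RmsCurve
    fit: GaussianFit | None


def in_plane_fiducials_at_z(
    fiducials: list, z: float
) -> dict[str, np.ndarray]:
    """Labeled (x, y) cross-sections of the fiducials at the axial plane ``z``.

    Line fiducials whose segment does not cross the plane are omitted; point
    fiducials are included only when the plane is within their z tolerance.
    """
    if not fiducials:
        raise ValueError("empty fiducial list")
    out: dict[str, np.ndarray] = {}
    for f in fiducials:
        if isinstance(f, PointFiducial):
            if abs(f.position[2] - z) <= f.z_tolerance:
                out[f.label] = f.position[:2].copy()
        elif isinstance(f, LineFiducial):
            p = intersect_line_with_plane(f, z)
            if p is not None:
                out[f.label] = p
        else:
            raise TypeError(f"unsupported fiducial type: {type(f).__name__}")
    return out


def rms_curve(
    hist_points: dict[str, np.ndarray],
    fiducials: list,
    z_grid: np.ndarray,
    allow_reflection: bool = False,
) -> RmsCurve:
    """Scan candidate planes and record the 2-D rigid-fit residual RMS at each.

    For every z in ``z_grid`` the fiducial cross-sections are matched to
    ``hist_points`` by label and a least-squares in-plane rigid registration
    is performed; planes sharing fewer than three labels with the histology
    slice are dropped from the curve.
    """
    z_grid = np.sort(np.asarray(z_grid, dtype=float))
    zs, rms, ns = [], [], []
    for z in z_grid:
        plane_pts = in_plane_fiducials_at_z(fiducials, z)
        shared = [l for l in hist_points if l in plane_pts]
        if len(shared) < MIN_PAIRS:
            continue
        corr = Correspondences2D(
            shared,
            np.array([hist_points[l] for l in shared]),
            np.array([plane_pts[l] for l in shared]),
        )
        fit: FitResult = fit_rigid_2d(corr, allow_reflection=allow_reflection)
        zs.append(z)
        rms.append(fit.rms)
        ns.append(len(shared))
    if not zs:
        raise InsufficientLandmarksError(
            "no candidate plane shares >= 3 labels with the histology slice"
        )
    return RmsCurve(np.array(zs), np.array(rms), np.array(ns))


def _neg_gaussian(params: np.ndarray, z: np.ndarray) -> np.ndarray:
    a, b, c, mu = params
    return a - b * np.exp(-((z - mu) ** 2) / c**2)


def fit_negative_gaussian(curve: RmsCurve) -> GaussianFit:
    """Bounded nonlinear least-squares fit of the dip model to an RMS curve.

    Initialization: ``a`` at the curve maximum, ``b`` at the observed depth,
    ``mu`` at the discrete argmin and ``c`` at half the z range; ``b`` and
    ``c`` are bounded away from zero.  A degenerate (flat) curve yields a
    depth pinned at its lower bound and ``converged=False`` rather than an
    exception.
    """
    if len(curve) < 4:
        raise InsufficientLandmarksError(
            f"dip fit needs >= 4 curve points (4 parameters), got {len(curve)}"
        )
    z, r = curve.z_values, curve.rms_values
    span = float(z[-1] - z[0])
    dz = curve.grid_spacing
    b_lo, c_lo = 1e-6, dz / 2.0
    x0 = np.array(
        [
            float(r.max()),
            max(float(r.max() - r.min()), b_lo * 2),
            max(span / 2.0, c_lo * 2),
            float(z[np.argmin(r)]),
        ]
    )
    lo = [-np.inf, b_lo, c_lo, z[0] - span]
    hi = [np.inf, np.inf, 10 * max(span, dz), z[-1] + span]
    x0 = np.clip(x0, lo, hi)
    try:
        sol = least_squares(
            lambda p: _neg_gaussian(p, z) - r, x0, bounds=(lo, hi), method="trf"
        )
    except Exception:
        return GaussianFit(*x0, converged=False)
    a, b, c, mu = (float(v) for v in sol.x)
    # a dip indistinguishable from flat noise is not a usable fit
    depth_floor = max(2 * b_lo, 1e-9 * max(abs(a), 1.0))
    converged = bool(sol.success) and b > depth_floor
    return GaussianFit(a, b, c, mu, converged=converged)


def find_corresponding_plane(curve: RmsCurve, window: int = 4) -> SliceMatch:
    """Pick the plane minimizing the RMS curve, via the Gaussian dip if possible.

    The dip model describes the curve only near its minimum -- away from the
    matching plane the residual grows roughly linearly with plane offset, not
    like a Gaussian tail -- so the fit is restricted to ``window`` grid steps
    on either side of the discrete argmin (the whole curve if it is shorter).
    When the fit converges with its centre inside the fitted z range,
    ``z_star = mu`` (sub-slice resolution) and ``rms_star = max(a - b, 0)``.
    Otherwise the discrete argmin of the curve is used; exact ties are broken
    toward the smallest z with a warning.
    """
    fit: GaussianFit | None = None
    sub = curve
    if window is not None and len(curve) > 2 * window + 1:
        i0 = int(np.argmin(curve.rms_values))
        lo, hi = max(0, i0 - window), min(len(curve), i0 + window + 1)
        sub = RmsCurve(
            curve.z_values[lo:hi],
            curve.rms_values[lo:hi],
            curve.n_points_used[lo:hi],
        )
    if len(sub) >= 4:
        fit = fit_negative_gaussian(sub)
        dz = sub.grid_spacing
        if fit.converged and sub.z_values[0] - dz <= fit.mu <= sub.z_values[-1] + dz:
            return SliceMatch(
                z_star=float(fit.mu),
                rms_star=max(fit.rms_at_min, 0.0),
                method="gaussian",
                curve=curve,
                fit=fit,
            )
    r = curve.rms_values
    i = int(np.argmin(r))
    if np.sum(r == r[i]) > 1:
        warnings.warn(
            "RMS curve has tied minima (degenerate, e.g. parallel fiducials); "
            "choosing the smallest z",
            stacklevel=2,
        )
        i = int(np.flatnonzero(r == r[i])[0])
    return SliceMatch(
        z_star=float(curve.z_values[i]),
        rms_star=float(r[i]),
        method="discrete_argmin",
        curve=curve,
        fit=fit,
    )
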