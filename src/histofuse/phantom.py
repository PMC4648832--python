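"""Seeded synthetic-specimen phantoms for end-to-end validation.

A phantom emulates an excised larynx specimen prepared for co-registration:

* 2-4 implanted line fiducials ("spines"), 20-30 mm long, mutually angled
  at about 30 degrees so their cross-section pattern changes shape along the
  cutting axis;
* 13 anatomical landmarks scattered through the specimen, observed in two
  frames related by a modest unknown rigid motion (the in vivo -> ex vivo
  repositioning) plus Gaussian localization noise;
* histology cut planes: a nominal axial plane, optionally tilted by up to a
  couple of degrees, whose fiducial cross-sections are re-expressed in an
  unknown in-plane mounting pose with in-plane localization noise.

Every stage draws from an independent, named substream of one master seed,
so phantom geometry, landmark noise and slice pose are individually
reproducible.

The phantoms are point/line geometry only: no voxelized images, no tissue
deformation or shrinkage, no tracer-uptake simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    LineFiducial,
    RigidTransform2D,
    RigidTransform3D,
    invert,
)
from .registration import Correspondences3D

__all__ = [
    "PhantomSpec",
    "Phantom",
    "SyntheticSlice",
    "make_phantom",
    "observe_landmarks",
    "cut_slice",
    "sample_slice_thicknesses",
    "SLICE_THICKNESS_MEAN_MM",
    "SLICE_THICKNESS_SD_MM",
]

# bandsaw slice thickness statistics of the emulated specimens (mm)
SLICE_THICKNESS_MEAN_MM = 5.28
SLICE_THICKNESS_SD_MM = 2.42

# substream indices of the master seed
_SUB_GEOMETRY = 0
_SUB_LANDMARK_NOISE = 1
_SUB_SLICE_POSE = 2
_SUB_THICKNESS = 3


def _rng(seed: int, substream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(substream, extra))
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults match the emulated study geometry."""

    n_spines: int = 4
    spine_length_range: tuple[float, float] = (20.0, 30.0)
    target_pairwise_angle: float = 30.0  # degrees
    n_landmarks: int = 13
    specimen_extent: tuple[float, float, float] = (60.0, 60.0, 50.0)
    ct_plane_spacing: float = 1.0
    landmark_noise_sd: float = 0.0
    inplane_noise_sd: float = 0.0
    slice_tilt_max: float = 2.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spines < 2:
            raise ValueError("need at least 2 spines")
        if self.n_landmarks < 4:
            raise ValueError("need at least 4 landmarks (leave-one-out minimum)")
        if min(self.landmark_noise_sd, self.inplane_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.ct_plane_spacing <= 0:
            raise ValueError("plane spacing must be > 0")


@dataclass(frozen=True)
class Phantom:
    spines: list
    landmarks_exvivo: dict[str, np.ndarray]
    gt_invivo_to_exvivo: RigidTransform3D
    spec: PhantomSpec
    pairwise_angles_deg: np.ndarray = field(default=None)

    def common_z_interval(self) -> tuple[float, float]:
        """The z range crossed by every spine (where all cross-sections exist)."""
        los, his = zip(*(s.z_extent() for s in self.spines))
        return (max(los), min(his))


@dataclass(frozen=True)
class SyntheticSlice:
    """One simulated histology slice with its ground truth."""

    z_true: float
    gt_inplane: RigidTransform2D
    hist_points: dict[str, np.ndarray]
    tilt_deg: float
    warning: bool = False  # fewer than 3 fiducials crossed the plane


def _spine_directions(
    rng: np.random.Generator, n: int, target_deg: float
) -> np.ndarray:
    """Unit directions with pairwise angles near ``target_deg``.

    Directions sit on a cone of half-angle target/2 about the cutting axis,
    at evenly spread azimuths with jitter; for a parallel bundle
    (target 0) all directions coincide with the axis.
    """
    if target_deg <= 0:
        return np.tile([0.0, 0.0, 1.0], (n, 1))
    polar = np.radians(target_deg / 2.0)
    azim = (
        rng.uniform(0, 2 * np.pi)
        + np.arange(n) * 2 * np.pi / n
        + rng.uniform(-0.15, 0.15, size=n)
    )
    polar_j = polar * rng.uniform(0.9, 1.1, size=n)
    return np.column_stack(
        [
            np.sin(polar_j) * np.cos(azim),
            np.sin(polar_j) * np.sin(azim),
            np.cos(polar_j),
        ]
    )


def _pairwise_angles_deg(dirs: np.ndarray) -> np.ndarray:
    cos = np.clip(dirs @ dirs.T, -1.0, 1.0)
    iu = np.triu_indices(len(dirs), k=1)
    return np.degrees(np.arccos(cos[iu]))


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom satisfying the angle and containment constraints.

    Spine geometry is rejection-sampled (bounded retries) until every
    pairwise angle is within 10 degrees of the target and every segment lies
    inside the specimen box.  The ground-truth in vivo -> ex vivo motion is
    small (rotation <= 20 degrees, translation <= 20 mm): specimens are
    positioned for the ex vivo scan so as to minimize orientation changes.
    """
    rng = _rng(spec.seed, _SUB_GEOMETRY)
    ex, ey, ez = spec.specimen_extent
    tol = 10.0  # degrees, allowed deviation of achieved pairwise angles

    spines = None
    angles = None
    for _ in range(1000):
        dirs = _spine_directions(rng, spec.n_spines, spec.target_pairwise_angle)
        angles = _pairwise_angles_deg(dirs)
        if spec.target_pairwise_angle > 0 and np.any(
            np.abs(angles - spec.target_pairwise_angle) > tol
        ):
            continue
        lengths = rng.uniform(*spec.spine_length_range, size=spec.n_spines)
        # origins in a disc around the specimen centre, near the bottom
        r = rng.uniform(0, min(ex, ey) / 6.0, size=spec.n_spines)
        phi = rng.uniform(0, 2 * np.pi, size=spec.n_spines)
        z0 = rng.uniform(0.1 * ez, 0.2 * ez, size=spec.n_spines)
        origins = np.column_stack(
            [ex / 2 + r * np.cos(phi), ey / 2 + r * np.sin(phi), z0]
        )
        ends = origins + lengths[:, None] * dirs
        lo = np.minimum(origins, ends)
        hi = np.maximum(origins, ends)
        if np.any(lo < 0) or np.any(hi > [ex, ey, ez]):
            continue
        spines = [
            LineFiducial(f"S{i+1}", origins[i], dirs[i], float(lengths[i]))
            for i in range(spec.n_spines)
        ]
        break
    if spines is None:
        raise RuntimeError(
            "could not satisfy spine angle/containment constraints in 1000 tries"
        )

    margin = 5.0
    lm = rng.uniform(
        [margin] * 3, [ex - margin, ey - margin, ez - margin], size=(spec.n_landmarks, 3)
    )
    landmarks = {f"L{i+1}": lm[i] for i in range(spec.n_landmarks)}

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, np.radians(20.0))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-20.0, 20.0, size=3)
    gt = RigidTransform3D(R, t)

    return Phantom(
        spines=spines,
        landmarks_exvivo=landmarks,
        gt_invivo_to_exvivo=gt,
        spec=spec,
        pairwise_angles_deg=angles,
    )


def observe_landmarks(
    p: Phantom, noise_sd: float, seed: int | None = None
) -> Correspondences3D:
    """Simulated landmark correspondences for the 3-D registration step.

    Source points are the landmarks pulled back to the "in vivo" frame by
    the inverse ground-truth motion; targets are the ex vivo landmarks with
    isotropic Gaussian localization noise of ``noise_sd`` mm.
    """
    rng = _rng(p.spec.seed if seed is None else seed, _SUB_LANDMARK_NOISE)
    labels = list(p.landmarks_exvivo)
    ex = np.array([p.landmarks_exvivo[l] for l in labels])
    src = invert(p.gt_invivo_to_exvivo).apply(ex)
    tgt = ex + rng.normal(0.0, noise_sd, size=ex.shape) if noise_sd > 0 else ex
    return Correspondences3D(labels, src, tgt)


def cut_slice(p: Phantom, z: float, seed: int | None = None) -> SyntheticSlice:
    """Simulate cutting and mounting a histology slice at nominal height ``z``.

    The cutting plane passes through the specimen-centre axis at ``z`` and is
    tilted about a random in-plane axis by up to ``slice_tilt_max`` degrees.
    Spine intersections with that plane, expressed in the plane's own 2-D
    frame, are moved by a random in-plane rigid transform (the unknown
    mounting pose of the section on the slide) and perturbed with in-plane
    Gaussian noise.  The nominal z, tilt and mounting pose are recorded as
    ground truth.
    """
    ex, ey, ez = p.spec.specimen_extent
    if not (0.0 <= z <= ez):
        raise ValueError(f"z={z} outside specimen extent [0, {ez}]")
    rng = _rng(
        p.spec.seed if seed is None else seed, _SUB_SLICE_POSE, int(round(z * 1000))
    )

    tilt = rng.uniform(0.0, np.radians(p.spec.slice_tilt_max))
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(phi), np.sin(phi), 0.0])  # in-plane tilt axis
    # normal: z axis rotated by `tilt` about `axis`
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    Rt = np.eye(3) + np.sin(tilt) * K + (1 - np.cos(tilt)) * (K @ K)
    normal = Rt @ np.array([0.0, 0.0, 1.0])
    p0 = np.array([ex / 2.0, ey / 2.0, z])  # plane anchor on the centre axis

    # in-plane basis of the tilted plane
    u = Rt @ np.array([1.0, 0.0, 0.0])
    v = np.cross(normal, u)

    pts: dict[str, np.ndarray] = {}
    for s in p.spines:
        denom = float(s.direction @ normal)
        if abs(denom) < 1e-12:
            continue
        tpar = float((p0 - s.origin) @ normal) / denom
        if tpar < 0.0 or tpar > s.length:
            continue
        q = s.origin + tpar * s.direction
        pts[s.label] = np.array([(q - p0) @ u, (q - p0) @ v])

    pose = RigidTransform2D(
        float(rng.uniform(-np.pi, np.pi)), rng.uniform(-10.0, 10.0, size=2)
    )
    hist: dict[str, np.ndarray] = {}
    for label, q in pts.items():
        h = pose.apply(q)
        if p.spec.inplane_noise_sd > 0:
            h = h + rng.normal(0.0, p.spec.inplane_noise_sd, size=2)
        hist[label] = h

    warn = len(hist) < 3
    if warn:
        warnings.warn(
            f"slice at z={z}: only {len(hist)} fiducial(s) crossed the plane",
            stacklevel=2,
        )
    return SyntheticSlice(
        z_true=float(z),
        gt_inplane=pose,
        hist_points=hist,
        tilt_deg=float(np.degrees(tilt)),
        warning=warn,
    )


def sample_slice_thicknesses(n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` bandsaw slice thicknesses (mm) from a truncated-at-zero
    normal with the study's mean 5.28 and SD 2.42 mm."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, _SUB_THICKNESS)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(SLICE_THICKNESS_MEAN_MM, SLICE_THICKNESS_SD_MM, size=n)
        draw = draw[draw > 0]
        take = min(n - filled, draw.size)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out
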