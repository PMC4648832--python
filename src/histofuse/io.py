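"""Readers and writers for the interchange formats, plus volume resampling.

Formats
-------
* Landmark CSV: ``label, x_mm, y_mm[, z_mm]``.  For ``space="histology"``
  coordinates may instead be in micrometre pixel units with the image row
  increasing downward; they are converted to mm with y increasing upward at
  this boundary (``y_mm = (image_height_px - row_px) * pixel_size_um / 1000``).
* Correspondence CSV: ``label, src_x, src_y[, src_z], tgt_x, tgt_y[, tgt_z]``.
* Line-fiducial CSV: ``label, ox_mm, oy_mm, oz_mm, dx, dy, dz, length_mm``.
* Transform JSON: ``{"matrix": 4x4 row-major, "from_space": ..., "to_space": ...}``.
* RMS-curve CSV: ``z_mm, rms_mm, n_points``.
* Error-report JSON: full :class:`~histofuse.error_model.ErrorReport` contents;
  unavailable totals serialize as ``null``.

Volumes are NIfTI (nibabel); world coordinates follow the RAS+ convention of
the file's affine.  All internal math is plain mm and convention-agnostic.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .error_model import ErrorReport, SampleErrors
from .geometry import GeometryError, LineFiducial, RigidTransform3D
from .registration import Correspondences2D, Correspondences3D

__all__ = [
    "ParseError",
    "Volume",
    "read_landmarks",
    "read_correspondences",
    "read_fiducials",
    "write_fiducials",
    "read_transform",
    "write_transform",
    "write_curve",
    "read_curve",
    "write_report",
    "read_report",
    "load_volume",
    "save_volume",
    "resample_volume",
]


class ParseError(ValueError):
    """Malformed interchange file; the message names the offending line."""


@dataclass(frozen=True)
class Volume:
    """A scalar image volume with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    space: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.affine, dtype=float)
        if A.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        object.__setattr__(self, "affine", A)
        object.__setattr__(self, "data", np.asarray(self.data))


def _rows(path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not row or not any(row) or row[0].startswith("#"):
                continue
            yield lineno, row


def _floats(row, start, lineno, path):
    try:
        return [float(c) for c in row[start:]]
    except ValueError as e:
        raise ParseError(f"{path}:{lineno}: non-numeric field ({e})") from None


def _maybe_header(row) -> bool:
    try:
        float(row[1])
        return False
    except (ValueError, IndexError):
        return True


def read_landmarks(
    path,
    space: str = "ct",
    pixel_size_um: float = 1.0,
    image_height_px: int | None = None,
) -> dict[str, np.ndarray]:
    """Labeled points in mm world coordinates.

    CT/PET spaces expect 3-D mm rows; histology expects 2-D rows, converted
    from micrometre pixel units (row axis down) when ``image_height_px`` is
    given, otherwise taken as mm already.
    """
    dim = 2 if space == "histology" else 3
    out: dict[str, np.ndarray] = {}
    for lineno, row in _rows(path):
        if lineno == 1 and _maybe_header(row):
            continue
        if len(row) != 1 + dim:
            raise ParseError(
                f"{path}:{lineno}: expected {1 + dim} fields, got {len(row)}"
            )
        label = row[0]
        if label in out:
            raise ParseError(f"{path}:{lineno}: duplicate label {label!r}")
        vals = _floats(row, 1, lineno, path)
        if space == "histology" and image_height_px is not None:
            col_px, row_px = vals
            vals = [
                col_px * pixel_size_um / 1000.0,
                (image_height_px - row_px) * pixel_size_um / 1000.0,
            ]
        out[label] = np.array(vals)
    if not out:
        raise ParseError(f"{path}: no landmark rows")
    return out


def read_correspondences(path):
    """Correspondence pairs; dimensionality (2-D/3-D) inferred from the width."""
    labels, src, tgt = [], [], []
    dim = None
    for lineno, row in _rows(path):
        if lineno == 1 and _maybe_header(row):
            continue
        if len(row) == 7:
            d = 3
        elif len(row) == 5:
            d = 2
        else:
            raise ParseError(
                f"{path}:{lineno}: expected 5 (2-D) or 7 (3-D) fields, got {len(row)}"
            )
        if dim is None:
            dim = d
        elif d != dim:
            raise ParseError(f"{path}:{lineno}: mixed 2-D and 3-D rows")
        vals = _floats(row, 1, lineno, path)
        labels.append(row[0])
        src.append(vals[:dim])
        tgt.append(vals[dim:])
    if dim is None:
        raise ParseError(f"{path}: no correspondence rows")
    cls = Correspondences3D if dim == 3 else Correspondences2D
    return cls(labels, np.array(src), np.array(tgt))


def read_fiducials(path) -> list[LineFiducial]:
    out = []
    for lineno, row in _rows(path):
        if lineno == 1 and _maybe_header(row):
            continue
        if len(row) != 8:
            raise ParseError(f"{path}:{lineno}: expected 8 fields, got {len(row)}")
        vals = _floats(row, 1, lineno, path)
        out.append(LineFiducial(row[0], vals[0:3], vals[3:6], vals[6]))
    if not out:
        raise ParseError(f"{path}: no fiducial rows")
    return out


def write_fiducials(fiducials: list[LineFiducial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "ox_mm", "oy_mm", "oz_mm", "dx", "dy", "dz", "length_mm"])
        for f in fiducials:
            w.writerow(
                [f.label, *(repr(float(v)) for v in f.origin), *(repr(float(v)) for v in f.direction), repr(float(f.length))]
            )


def write_transform(T: RigidTransform3D, path, from_space: str = "", to_space: str = "") -> None:
    payload = {
        "matrix": T.matrix.tolist(),
        "from_space": from_space,
        "to_space": to_space,
    }
    _atomic_json(payload, path)


def read_transform(path) -> tuple[RigidTransform3D, str, str]:
    with open(path) as fh:
        payload = json.load(fh)
    T = RigidTransform3D.from_matrix(np.array(payload["matrix"]))
    return T, payload.get("from_space", ""), payload.get("to_space", "")


def write_curve(curve, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["z_mm", "rms_mm", "n_points"])
        for z, r, n in zip(curve.z_values, curve.rms_values, curve.n_points_used):
            w.writerow([repr(float(z)), repr(float(r)), int(n)])


def read_curve(path):
    from .slice_match import RmsCurve

    z, r, n = [], [], []
    for lineno, row in _rows(path):
        if lineno == 1 and _maybe_header(row):
            continue
        vals = _floats(row, 0, lineno, path)
        z.append(vals[0])
        r.append(vals[1])
        n.append(int(vals[2]))
    return RmsCurve(np.array(z), np.array(r), np.array(n, dtype=int))


def _atomic_json(payload, path) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    os.replace(tmp, path)


def write_report(r: ErrorReport, path) -> None:
    """Serialize a report to JSON; NA components/totals become ``null``."""
    payload = {
        "mode": r.mode,
        "pet_ct_error_mm": r.pet_ct_error,
        "rows": [
            {
                "sample_id": row.sample_id,
                "ctin_ctex_mm": row.ctin_ctex,
                "ctex_hist_mm": row.ctex_hist,
                "total_mm": row.total,
            }
            for row in r.rows
        ],
        "summary": {
            "mean_ctin_ctex_mm": r.mean_ctin_ctex,
            "sd_ctin_ctex_mm": r.sd_ctin_ctex,
            "mean_ctex_hist_mm": r.mean_ctex_hist,
            "sd_ctex_hist_mm": r.sd_ctex_hist,
            "mean_total_mm": r.mean_total,
            "sd_total_mm": r.sd_total,
            "overall_pet_hist_mm": r.overall_pet_hist,
        },
        "notes": list(r.notes),
    }
    _atomic_json(payload, path)


def read_report(path) -> ErrorReport:
    with open(path) as fh:
        p = json.load(fh)
    rows = [
        SampleErrors(
            row["sample_id"],
            row["ctin_ctex_mm"],
            row["ctex_hist_mm"],
            row["total_mm"],
        )
        for row in p["rows"]
    ]
    s = p["summary"]
    return ErrorReport(
        rows=rows,
        mean_ctin_ctex=s["mean_ctin_ctex_mm"],
        sd_ctin_ctex=s["sd_ctin_ctex_mm"],
        mean_ctex_hist=s["mean_ctex_hist_mm"],
        sd_ctex_hist=s["sd_ctex_hist_mm"],
        mean_total=s["mean_total_mm"],
        sd_total=s["sd_total_mm"],
        overall_pet_hist=s["overall_pet_hist_mm"],
        pet_ct_error=p["pet_ct_error_mm"],
        mode=p["mode"],
        notes=list(p.get("notes", [])),
    )


def load_volume(path, space: str = "") -> Volume:
    img = nib.load(path)
    return Volume(np.asanyarray(img.dataobj), img.affine, space)


def save_volume(v: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data), v.affine), path)


def resample_volume(
    v: Volume,
    T: RigidTransform3D,
    target: Volume,
    interpolation: str = "trilinear",
) -> Volume:
    """Resample ``v`` after the world-space motion ``T`` onto ``target``'s grid.

    Each target voxel centre is mapped to world coordinates, pulled back
    through ``T`` inverse, and sampled in ``v`` (nearest neighbour or
    trilinear); samples outside ``v`` are zero.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    # voxel(target) -> world -> inverse motion -> voxel(source)
    M = np.linalg.inv(v.affine) @ np.linalg.inv(T.matrix) @ target.affine
    ii, jj, kk = np.meshgrid(
        *(np.arange(n) for n in target.data.shape), indexing="ij"
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (M @ vox)[:3]
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float), src, order=order, mode="constant", cval=0.0
    )
    return Volume(out.reshape(target.data.shape), target.affine.copy(), target.space)
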