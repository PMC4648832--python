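"""Registration-error estimation and propagation.

Three error components separate the modalities in the pipeline:

* PET -> in vivo CT: taken as the scanner's hardware alignment accuracy,
  a configurable constant (default 1.0 mm) -- no landmark data exists to
  measure it per sample.
* in vivo CT -> ex vivo CT: estimated per specimen by leave-one-out over the
  anatomical landmarks (an approximation of target registration error, TRE).
* ex vivo CT -> histology: approximated by the residual in-plane RMS
  inter-marker distance of the matched slice (fiducial registration error,
  FRE) -- the spines are too few and too extended for a leave-one-out.

Independent components combine in quadrature (square root of the sum of
squares).  ``build_report`` assembles a per-sample table with column
summaries; *reproduce* mode computes on inputs as printed at two decimals
and rounds results the same way, *research* mode keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .registration import (
    Correspondences3D,
    InsufficientLandmarksError,
    fit_rigid_3d,
)

__all__ = [
    "LooResult",
    "SampleErrors",
    "ErrorReport",
    "loo_error",
    "quadrature_total",
    "summarize",
    "build_report",
]


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out landmark error: one held-out distance per landmark."""

    labels: list
    per_landmark_errors: np.ndarray
    mean_error: float


@dataclass(frozen=True)
class SampleErrors:
    """Per-sample step errors (mm). ``ctin_ctex`` may be unavailable
    (specimens without implanted fiducials cannot be chained to in vivo CT)."""

    sample_id: str
    ctin_ctex: float | None
    ctex_hist: float
    total: float | None = None


@dataclass(frozen=True)
class ErrorReport:
    """Per-sample rows plus column summaries and the overall PET->histology error."""

    rows: list
    mean_ctin_ctex: float
    sd_ctin_ctex: float
    mean_ctex_hist: float
    sd_ctex_hist: float
    mean_total: float
    sd_total: float
    overall_pet_hist: float
    pet_ct_error: float
    mode: str
    notes: list = field(default_factory=list)


def loo_error(c: Correspondences3D) -> LooResult:
    """Mean leave-one-out landmark error of a 3-D rigid registration.

    For each landmark the fit is redone on the remaining pairs, the held-out
    source point is mapped by that transform, and its distance to the true
    target is recorded; the mean over all landmarks is returned.  Unlike the
    residual RMS of the full fit (FRE), which is optimistic because every
    point influenced the transform, this approximates the error at a point
    that did not drive the fit (TRE).
    """
    if len(c) < 4:
        raise InsufficientLandmarksError(
            f"leave-one-out needs >= 4 pairs (each sub-fit needs 3), got {len(c)}"
        )
    errs = []
    for i, label in enumerate(c.labels):
        fit = fit_rigid_3d(c.drop(label))
        moved = fit.transform.apply(c.source[i])
        errs.append(float(np.linalg.norm(moved - c.target[i])))
    errs = np.asarray(errs)
    return LooResult(list(c.labels), errs, float(errs.mean()))


def quadrature_total(components) -> float:
    """Combine independent error components: sqrt of the sum of squares."""
    comps = np.asarray(list(components), dtype=float)
    if comps.size == 0:
        raise ValueError("quadrature_total requires at least one component")
    if np.any(comps < 0):
        raise ValueError("error components must be >= 0")
    return float(np.sqrt(np.sum(comps**2)))


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("sd needs at least 2 values")
    return float(vals.mean()), float(vals.std(ddof=1))


def _round(x: float, nd: int, mode: str) -> float:
    return round(x, nd) if mode == "reproduce" else x


def build_report(
    rows, pet_ct_error: float = 1.0, mode: str = "research"
) -> ErrorReport:
    """Assemble the per-sample error table and the overall PET->histology error.

    ``rows`` is an iterable of ``(sample_id, ctin_ctex_or_None, ctex_hist)``
    or :class:`SampleErrors`.  Rows missing the in-vivo/ex-vivo component get
    no total and are excluded from the total-column summary; the ex-vivo ->
    histology column is summarized over all rows.  The overall error adds the
    constant PET-CT alignment term to the mean total in quadrature, once --
    it is a property of the scanner, not of a specimen.
    """
    if mode not in ("reproduce", "research"):
        raise ValueError(f"mode must be 'reproduce' or 'research', got {mode!r}")
    if pet_ct_error < 0:
        raise ValueError("pet_ct_error must be >= 0")
    parsed: list[SampleErrors] = []
    for r in rows:
        if isinstance(r, SampleErrors):
            sid, a, b = r.sample_id, r.ctin_ctex, r.ctex_hist
        else:
            sid, a, b = r
        if a is not None and (isinstance(a, float) and math.isnan(a)):
            a = None
        total = None
        if a is not None:
            total = _round(quadrature_total([a, b]), 2, mode)
        parsed.append(SampleErrors(str(sid), a, float(b), total))
    totals = [r.total for r in parsed if r.total is not None]
    if not totals:
        raise ValueError("no row has both error components; overall undefined")
    ctin = [r.ctin_ctex for r in parsed if r.ctin_ctex is not None]
    chist = [r.ctex_hist for r in parsed]
    mean_ct, sd_ct = summarize(ctin)
    mean_ch, sd_ch = summarize(chist)
    mean_tot, sd_tot = summarize(totals)
    overall = quadrature_total([mean_tot, pet_ct_error])
    notes = []
    if mode == "research":
        # spread of per-sample overall errors, for context; the study-style
        # summary quotes the spread of totals instead
        per_sample_overall_sd = float(
            np.std([quadrature_total([t, pet_ct_error]) for t in totals], ddof=1)
        )
        notes.append(
            "sd of per-sample sqrt(total^2 + pet_ct^2) = "
            f"{per_sample_overall_sd:.3f} mm; this is not the same quantity "
            "as the sd of the total column"
        )
    return ErrorReport(
        rows=parsed,
        mean_ctin_ctex=_round(mean_ct, 2, mode),
        sd_ctin_ctex=_round(sd_ct, 2, mode),
        mean_ctex_hist=_round(mean_ch, 2, mode),
        sd_ctex_hist=_round(sd_ch, 2, mode),
        mean_total=_round(mean_tot, 2, mode),
        sd_total=_round(sd_tot, 2, mode),
        overall_pet_hist=_round(overall, 1, mode),
        pet_ct_error=float(pet_ct_error),
        mode=mode,
        notes=notes,
    )
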