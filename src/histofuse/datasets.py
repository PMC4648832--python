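"""Small bundled datasets.

The one dataset shipped is the per-sample registration-error table of a
six-subject laryngeal-cancer PET/histopathology co-registration study: for
each histology sample, the landmark-based in vivo CT -> ex vivo CT error
(leave-one-out mean, mm) and the ex vivo CT -> histology error (residual
in-plane RMS inter-marker distance, mm), as published at two decimal
places.  Subjects P1 and P2 received no implanted fiducial markers, so
their in vivo -> ex vivo component is unavailable (NA).

It serves as the reference input for the report-building arithmetic: the
derived Total column, the column summaries and the overall PET->histology
error are recomputed from it, not stored.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["laryngeal_study_errors"]

_LARYNGEAL_STUDY_CSV = """\
sample_id,ctin_ctex_mm,ctex_hist_mm
P1-BH,,0.91
P1-BJ,,1.86
P1-BK,,1.52
P2-B,,0.38
P2-C,,0.92
P3-BJ,3.55,1.08
P3-BH,3.55,0.58
P3-BK,3.55,0.11
P4-AA,2.83,0.80
P4-AB,2.83,0.85
P4-AC,2.83,0.97
P4-R,2.83,0.75
P5-M1,2.94,1.08
P5-M2,2.94,0.49
P5-S,2.94,1.14
P6-CC,1.84,1.09
P6-CD,1.84,0.89
P6-DB,1.84,0.50
P6-DC,1.84,0.62
P6-DD,1.84,0.83
"""


def laryngeal_study_errors() -> pd.DataFrame:
    """The published per-sample step errors (mm), one row per histology sample.

    Columns: ``sample_id``, ``ctin_ctex_mm`` (NaN where no fiducial markers
    were implanted), ``ctex_hist_mm``.
    """
    return pd.read_csv(io.StringIO(_LARYNGEAL_STUDY_CSV))
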