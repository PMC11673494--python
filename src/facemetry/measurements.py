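"""Soft-tissue anthropometric measurements.

Nineteen clinically standard items computed from a named landmark set in
an anatomical frame: six angles (nasolabial, facial convexity, total
facial convexity, outer-canthal-nasal, nasal, nasofrontal; degrees) and
thirteen linear items (mm).  Sagittal "depth" items (lip protrusions,
vermilion thicknesses, mentolabial furrow, philtral depth) are absolute
differences of the anterior-posterior (frame Z) coordinates; widths,
heights and lengths are Euclidean distances between their two landmarks
by default, with axis-projected variants available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .core import LandmarkSet
from .errors import DegenerateInputError, InvalidArgumentError
from .registration import AnatomicalFrame, build_frame

#: measurement names in report order; angles first
ANGLE_NAMES = (
    "nasolabial_angle",
    "facial_convexity",
    "total_facial_convexity",
    "outercanthal_nasal_angle",
    "nasal_angle",
    "nasofrontal_angle",
)
LINEAR_NAMES = (
    "outercanthal_width",
    "labial_fissure_width",
    "philtral_length",
    "philtral_width",
    "philtral_depth",
    "facial_height",
    "upper_lip_height",
    "lower_lip_height",
    "upper_lip_protrusion",
    "lower_lip_protrusion",
    "mentolabial_furrow_depth",
    "upper_vermilion_thickness",
    "lower_vermilion_thickness",
)
ALL_MEASUREMENTS = ANGLE_NAMES + LINEAR_NAMES

# (apex, p, q) triples for the angle items
_ANGLES = {
    "nasolabial_angle": ("Sn", "Prn", "Ls"),
    "facial_convexity": ("Sn", "Gl", "Pg'"),
    "total_facial_convexity": ("Prn", "Gl", "Pg'"),
    "outercanthal_nasal_angle": ("Sn", "ExL", "ExR"),
    "nasal_angle": ("Prn", "N'", "Sn"),
    "nasofrontal_angle": ("N'", "Gl", "Prn"),
}

# (a, b) pairs for distance items; axis is the projection axis used when
# projected=True (None = always Euclidean)
_DISTANCES = {
    "outercanthal_width": ("ExL", "ExR", "x"),
    "labial_fissure_width": ("LCh", "RCh", "x"),
    "philtral_length": ("Sn", "Ls", None),
    "philtral_width": ("CphL", "CphR", "x"),
    "facial_height": ("N'", "Gn'", "y"),
    "upper_lip_height": ("Sn", "Stos", "y"),
    "lower_lip_height": ("Stoi", "Sl", "y"),
}

# (a, b) pairs measured as |z_a - z_b| in the frame
_Z_ITEMS = {
    "upper_lip_protrusion": ("Prn", "Ls"),
    "lower_lip_protrusion": ("Prn", "Li"),
    "mentolabial_furrow_depth": ("Li", "Sl"),
    "upper_vermilion_thickness": ("Ls", "Stos"),
    "lower_vermilion_thickness": ("Li", "Stoi"),
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def angle_at(apex, p, q) -> float:
    """Angle at ``apex`` subtended by points ``p`` and ``q``, in degrees."""
    apex = np.asarray(apex, float)
    u = np.asarray(p, float) - apex
    v = np.asarray(q, float) - apex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateInputError("angle points coincide with the apex")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class MeasurementReport:
    """Values (mm or degrees) for the 19 soft-tissue items; items whose
    landmarks were unavailable are listed in ``missing``."""

    values: Dict[str, float] = field(default_factory=dict)
    missing: Set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        s = pd.Series(
            {n: self.values.get(n, np.nan) for n in ALL_MEASUREMENTS}, name="value"
        )
        return s


def measure_all(
    landmarks: LandmarkSet,
    frame: Optional[AnatomicalFrame] = None,
    projected: bool = False,
) -> MeasurementReport:
    """Compute the full measurement report.

    ``frame`` defaults to the anatomical frame built from the landmarks
    themselves; it is needed for the sagittal (|.|z) items and for
    projected distances.  Items whose landmarks are missing are flagged
    rather than failing the whole report.
    """
    if frame is None:
        frame = build_frame(landmarks)
    report = MeasurementReport()

    def get_z(name: str) -> float:
        return float(frame.coords(landmarks[name])[0, 2])

    for mname, (apex, p, q) in _ANGLES.items():
        try:
            report.values[mname] = angle_at(landmarks[apex], landmarks[p], landmarks[q])
        except KeyError:
            report.missing.add(mname)

    for mname, (a, b, axis) in _DISTANCES.items():
        try:
            pa, pb = landmarks[a], landmarks[b]
        except KeyError:
            report.missing.add(mname)
            continue
        if projected and axis is not None:
            ca = frame.coords(pa)[0, _AXIS_INDEX[axis]]
            cb = frame.coords(pb)[0, _AXIS_INDEX[axis]]
            report.values[mname] = float(abs(ca - cb))
        else:
            report.values[mname] = float(np.linalg.norm(pa - pb))

    for mname, (a, b) in _Z_ITEMS.items():
        try:
            report.values[mname] = float(abs(get_z(a) - get_z(b)))
        except KeyError:
            report.missing.add(mname)

    # philtral depth: sagittal depth of the philtral floor against the
    # midpoint of the crista philtri ridge line
    try:
        mid_z = float(
            frame.coords(0.5 * (landmarks["CphL"] + landmarks["CphR"]))[0, 2]
        )
        report.values["philtral_depth"] = float(abs(get_z("PhiF") - mid_z))
    except KeyError:
        report.missing.add("philtral_depth")
    return report


def compare_measurement_sets(
    reports_a: Sequence[MeasurementReport],
    reports_b: Sequence[MeasurementReport],
    paired: bool = True,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Group comparison of two lists of measurement reports.

    Returns one row per measurement with each group's mean ± SD, the
    paired differences (a − b) mean ± SD, the paired t statistic, its
    two-sided p value, and a significance star at ``alpha`` (optionally
    Bonferroni-adjusted across the measurements tested).
    """
    from .stats import paired_t_from_pairs

    if paired and len(reports_a) != len(reports_b):
        raise InvalidArgumentError("paired comparison requires equal-length lists")
    if not reports_a or not reports_b:
        raise InvalidArgumentError("need at least one report per group")

    a_df = pd.DataFrame([r.as_series() for r in reports_a])
    b_df = pd.DataFrame([r.as_series() for r in reports_b])
    rows: List[dict] = []
    tested = [n for n in ALL_MEASUREMENTS if a_df[n].notna().any() and b_df[n].notna().any()]
    thresh = alpha / len(tested) if (bonferroni and tested) else alpha
    for name in ALL_MEASUREMENTS:
        xa = a_df[name].dropna().to_numpy()
        xb = b_df[name].dropna().to_numpy()
        row = {
            "measurement": name,
            "mean_a": xa.mean() if xa.size else np.nan,
            "sd_a": xa.std(ddof=1) if xa.size > 1 else np.nan,
            "mean_b": xb.mean() if xb.size else np.nan,
            "sd_b": xb.std(ddof=1) if xb.size > 1 else np.nan,
        }
        if paired and xa.size == xb.size and xa.size >= 2:
            res = paired_t_from_pairs(xa, xb)
            # differences below numerical precision are never starred
            row.update(
                mean_diff=res.mean_diff,
                sd_diff=res.sd_diff,
                t=res.t,
                p=res.p,
                significant=bool(res.p < thresh and abs(res.mean_diff) > 1e-9),
            )
        else:
            row.update(mean_diff=np.nan, sd_diff=np.nan, t=np.nan, p=np.nan,
                       significant=False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("measurement")
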