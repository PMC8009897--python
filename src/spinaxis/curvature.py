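"""Spinal curvature estimation: Cobb, Ferguson, Greenspan index, Diab.

All four constructions operate on the extracted medial axis (MA) and central
sacral line (CSL) rather than on manually digitized endplates:

* **Cobb** — angle between MA tangent lines at the most-tilted rows of the
  curve's upper and lower limbs (the centerline equivalent of the classical
  endplate construction; the limiting vertebrae are by definition the most
  oblique ones).
* **Ferguson** — 180° minus the interior angle at the apical vertebra
  between rays to the two end-vertebra centers, so a collinear (straight)
  spine scores 0°.
* **Greenspan index** — cumulative |MA − CSL| displacement over the curve,
  normalized by the end-to-end chord length; a dimensionless deformity
  index, not an angle.
* **Diab** — like Ferguson but with each end-vertebra center replaced by the
  mean MA position over three nominal vertebra bands at that curve end.

Severity follows the clinical bands: below 10° is not scoliosis; 10–20°
mild, 20–40° moderate, 40° and above severe.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .axes import CentralSacralLine, MedialAxisSeries
from .errors import ValidationError
from .landmarks import CurveSegment, LandmarkSet, VERTEBRA_NAMES

__all__ = [
    "AngleReport",
    "tangent_slope",
    "cobb_angle",
    "ferguson_angle",
    "greenspan_index",
    "diab_angle",
    "classify_severity",
    "measure_segment",
]

METHODS = ("cobb", "ferguson", "greenspan", "diab")
SEVERITIES = ("normal", "mild", "moderate", "severe")

Point = tuple[float, float]  # (row, x)


@dataclass
class AngleReport:
    """One curvature estimate.

    ``value`` is in degrees for cobb/ferguson/diab and dimensionless for the
    greenspan index (whose ``severity`` is None — no degree mapping exists).
    """

    method: str
    value: float
    severity: str | None
    segment: CurveSegment | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")


def classify_severity(angle: float) -> str:
    """Clinical severity band of an angle in degrees.

    <10 normal (not scoliosis), [10, 20) mild, [20, 40) moderate,
    >=40 severe. Closed-left intervals resolve the band edges at exactly
    10, 20 and 40 degrees.
    """
    if angle < 0:
        raise ValidationError("angle must be non-negative")
    if angle < 10:
        return "normal"
    if angle < 20:
        return "mild"
    if angle < 40:
        return "moderate"
    return "severe"


def tangent_slope(
    ma: MedialAxisSeries, row: float, half_window: float = 25.0
) -> float:
    """Local slope dx/dy of the medial axis at ``row``.

    A quadratic least-squares fit of x against row over
    ``[row - half_window, row + half_window]`` (clipped to the MA extent),
    differentiated at ``row``. The quadratic term removes the bias a linear
    fit incurs exactly where Cobb tangents are taken — at slope extrema.
    """
    sel = np.abs(ma.rows - row) <= half_window + 1e-9
    n = int(sel.sum())
    if n < 3:
        raise ValidationError(
            f"tangent window at row {row} holds {n} samples (< 3)"
        )
    t = ma.rows[sel] - row
    deg = 2 if n >= 4 else min(2, n - 1)
    coef = np.polyfit(t, ma.x[sel], deg)
    # derivative of the fitted polynomial at t = 0 is the linear coefficient
    return float(coef[-2])


def _slope_series(ma: MedialAxisSeries, half_window: float) -> np.ndarray:
    """Savitzky–Golay first derivative of x(row) at every MA sample.

    Equivalent to :func:`tangent_slope` at interior rows, vectorized;
    requires (and the medial axis guarantees) uniform row spacing.
    """
    steps = np.diff(ma.rows)
    if not np.allclose(steps, steps[0]):
        raise ValidationError("slope series requires uniformly spaced rows")
    delta = float(steps[0])
    window = int(2 * round(half_window / delta) + 1)
    window = min(window, len(ma) if len(ma) % 2 == 1 else len(ma) - 1)
    window = max(window, 3)
    poly = min(2, window - 1)
    return savgol_filter(ma.x, window, poly, deriv=1, delta=delta, mode="interp")


def _angle_between_slopes(s1: float, s2: float) -> float:
    return abs(math.degrees(math.atan(s1) - math.atan(s2)))


def cobb_angle(
    ma: MedialAxisSeries,
    segment: CurveSegment,
    half_window: float = 25.0,
    endpoint_rule: str = "max_tilt",
) -> AngleReport:
    """Angle between MA tangents bounding the curve.

    ``endpoint_rule="max_tilt"`` (default) takes the tangents at the rows of
    maximal |slope| within [start, apex] and [apex, end] — the most oblique
    (limiting) vertebrae, matching the clinical construction. ``"bounds"``
    takes them literally at the segment's start and end rows.
    """
    if endpoint_rule not in ("max_tilt", "bounds"):
        raise ValidationError("endpoint_rule must be 'max_tilt' or 'bounds'")
    slopes = _slope_series(ma, half_window)
    if endpoint_rule == "bounds":
        s1 = tangent_slope(ma, segment.start_row, half_window)
        s2 = tangent_slope(ma, segment.end_row, half_window)
    else:
        up = (ma.rows >= segment.start_row) & (ma.rows <= segment.apex_row)
        lo = (ma.rows >= segment.apex_row) & (ma.rows <= segment.end_row)
        if not up.any() or not lo.any():
            raise ValidationError("segment does not intersect the MA")
        s1 = float(slopes[up][np.argmax(np.abs(slopes[up]))])
        s2 = float(slopes[lo][np.argmax(np.abs(slopes[lo]))])
    value = _angle_between_slopes(s1, s2)
    return AngleReport("cobb", value, classify_severity(value), segment)


def ferguson_angle(
    sev: Point, av: Point, iev: Point, segment: CurveSegment | None = None
) -> AngleReport:
    """180° minus the interior angle at the apex between rays to the ends."""
    a = np.asarray(av, float)
    v1 = np.asarray(sev, float) - a
    v2 = np.asarray(iev, float) - a
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValidationError("apex coincides with an end vertebra")
    cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    value = 180.0 - math.degrees(math.acos(cosang))
    return AngleReport("ferguson", value, classify_severity(value), segment)


def greenspan_index(
    ma: MedialAxisSeries, csl: CentralSacralLine, segment: CurveSegment
) -> AngleReport:
    """Cumulative normalized displacement of MA samples from the CSL.

    value = (sum of |MA x − CSL x| over the segment's rows) / L, with L the
    Euclidean distance between the MA points at the segment's start and end
    rows. Dimensionless; scale-invariant at a fixed per-segment sample
    count (when comparing geometries of different size, resample to the
    same number of rows).
    """
    sel = (ma.rows >= segment.start_row) & (ma.rows <= segment.end_row)
    if not sel.any():
        raise ValidationError("segment does not intersect the MA")
    d = ma.x[sel] - csl.x
    p1 = np.array([segment.start_row, ma.x_at(segment.start_row)])
    p2 = np.array([segment.end_row, ma.x_at(segment.end_row)])
    length = float(np.linalg.norm(p2 - p1))
    if length < 1e-12:
        raise ValidationError("zero end-to-end length")
    value = float(np.abs(d).sum() / length)
    return AngleReport("greenspan", value, None, segment)


def diab_angle(
    ma: MedialAxisSeries,
    segment: CurveSegment,
    band_height: float | None = None,
) -> AngleReport:
    """Apex-centered angle using three-vertebra mean anchors at each end.

    The upper anchor is the mean MA point over the three nominal vertebra
    bands at the curve's superior end, the lower anchor likewise at the
    inferior end; the value is 180° minus the interior angle at the apical
    vertebra between rays to the anchors. ``band_height`` defaults to the
    column extent divided by 17 (one nominal vertebra). The two three-band
    windows may overlap mid-segment, but each must fit within the segment.
    """
    if band_height is None:
        band_height = (ma.bottom_row - ma.top_row + 1) / len(VERTEBRA_NAMES)
    if band_height <= 0:
        raise ValidationError("band_height must be positive")
    span = segment.end_row - segment.start_row
    if 3 * band_height > span:
        raise ValidationError(
            "segment too short for three vertebra bands at each end"
        )
    up = (ma.rows >= segment.start_row) & (
        ma.rows <= segment.start_row + 3 * band_height
    )
    lo = (ma.rows >= segment.end_row - 3 * band_height) & (
        ma.rows <= segment.end_row
    )
    upper = np.array([ma.rows[up].mean(), ma.x[up].mean()])
    lower = np.array([ma.rows[lo].mean(), ma.x[lo].mean()])
    apex = np.array([segment.apex_row, ma.x_at(segment.apex_row)])
    v1, v2 = upper - apex, lower - apex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValidationError("apex coincides with a band anchor")
    cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    value = 180.0 - math.degrees(math.acos(cosang))
    return AngleReport("diab", value, classify_severity(value), segment)


def measure_segment(
    ma: MedialAxisSeries,
    csl: CentralSacralLine,
    segment: CurveSegment,
    landmarks: LandmarkSet,
    half_window: float = 25.0,
    diab_band_height: float | None = None,
) -> dict[str, AngleReport]:
    """All four curvature estimates for one segment.

    Methods that cannot be constructed on this segment (e.g. Diab on a very
    short curve) are reported as an :class:`AngleReport` with ``value``
    ``nan`` and severity None rather than aborting the remaining methods.
    """
    out: dict[str, AngleReport] = {}
    try:
        out["cobb"] = cobb_angle(ma, segment, half_window)
    except ValidationError:
        out["cobb"] = AngleReport("cobb", float("nan"), None, segment)
    try:
        out["ferguson"] = ferguson_angle(
            landmarks.sev, landmarks.av, landmarks.iev, segment
        )
    except ValidationError:
        out["ferguson"] = AngleReport("ferguson", float("nan"), None, segment)
    try:
        out["greenspan"] = greenspan_index(ma, csl, segment)
    except ValidationError:
        out["greenspan"] = AngleReport("greenspan", float("nan"), None, segment)
    try:
        out["diab"] = diab_angle(ma, segment, diab_band_height)
    except ValidationError:
        out["diab"] = AngleReport("diab", float("nan"), None, segment)
    return out
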