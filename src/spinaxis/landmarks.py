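"""Automatic end-vertebra and apex detection from the displacement signal.

A scoliotic curve shows up as an excursion of the medial axis away from the
central sacral line: the curve opens where |d| first exceeds a tolerance
(superior end vertebra, SEV), peaks at the apical vertebra (AV, the row of
maximal |d|) and closes where |d| returns within tolerance (inferior end
vertebra, IEV). A sign change of d splits adjacent curves of an S-shaped
(double) deformity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .axes import DisplacementSeries
from .errors import ValidationError

__all__ = [
    "CurveSegment",
    "LandmarkSet",
    "VERTEBRA_NAMES",
    "detect_curves",
    "apical_vertebra",
    "label_vertebrae",
    "full_extent_segment",
]

#: Thoracolumbar levels, superior to inferior: 12 thoracic + 5 lumbar.
VERTEBRA_NAMES: tuple[str, ...] = tuple(
    [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
)


@dataclass(frozen=True)
class CurveSegment:
    """One detected scoliotic curve: SEV row, AV row, IEV row."""

    start_row: float
    apex_row: float
    end_row: float
    direction: int
    max_displacement: float
    truncated: bool = False

    def __post_init__(self):
        if not self.start_row <= self.apex_row <= self.end_row:
            raise ValidationError("require start_row <= apex_row <= end_row")
        if self.start_row >= self.end_row:
            raise ValidationError("degenerate segment: start_row >= end_row")


@dataclass
class LandmarkSet:
    """SEV / AV / IEV positions, each ``(row, x)``, with optional level names."""

    sev: tuple[float, float]
    av: tuple[float, float]
    iev: tuple[float, float]
    vertebra_labels: dict[str, str] | None = field(default=None)


def detect_curves(
    disp: DisplacementSeries,
    epsilon: float = 2.0,
    min_span: float = 30.0,
) -> list[CurveSegment]:
    """Scan the displacement series top-to-bottom for curve excursions.

    Parameters
    ----------
    disp : DisplacementSeries
        Signed MA − CSL offsets per row.
    epsilon : float
        Tolerance in pixels below which the MA is considered to overlap the
        CSL. A curve opens at the last row before |d| exceeds it and closes
        where |d| returns to <= epsilon; a sign change of d closes the
        current segment and opens the next.
    min_span : float
        Segments spanning fewer rows are discarded as noise blips
        (a scoliotic curve spans several vertebrae by definition).

    Returns
    -------
    list of CurveSegment, superior to inferior. An empty list means no
    scoliotic curve (straight spine). A curve still open at the bottom of
    the column is closed at the last row and flagged ``truncated``.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    rows, d = disp.rows, disp.d
    segments: list[CurveSegment] = []

    def close(start: float, end: float, sgn: int, truncated: bool) -> None:
        if end - start < min_span:
            return
        sel = (rows >= start) & (rows <= end)
        # apex = max displacement in the segment's own direction, so a
        # boundary row shared with an adjacent opposite curve cannot win
        i = int(np.argmax(sgn * d[sel]))
        apex = float(rows[sel][i])
        peak = float(d[sel][i])
        segments.append(
            CurveSegment(
                start_row=float(start),
                apex_row=apex,
                end_row=float(end),
                direction=sgn,
                max_displacement=abs(peak),
                truncated=truncated,
            )
        )

    inside = False
    start = rows[0]
    sign = 0
    for i in range(len(rows)):
        if not inside:
            if abs(d[i]) > epsilon:
                inside = True
                sign = 1 if d[i] > 0 else -1
                start = rows[i - 1] if i > 0 else rows[i]
        else:
            if abs(d[i]) <= epsilon:
                close(start, rows[i], sign, truncated=False)
                inside = False
            elif (1 if d[i] > 0 else -1) != sign:
                # abrupt sign flip without passing through the epsilon band
                close(start, rows[i - 1], sign, truncated=False)
                start = rows[i - 1]
                sign = -sign
    if inside:
        close(start, rows[-1], sign, truncated=True)
    return segments


def apical_vertebra(
    disp: DisplacementSeries, segment: CurveSegment, refine: bool = False
) -> tuple[float, float]:
    """Row of maximal |d| within the segment (ties to the smallest row) and
    the MA x-coordinate there.

    With ``refine=True`` the raw maximum is polished by fitting a parabola
    to d over a window of ±20% of the segment span around it and taking the
    vertex (clamped to the window). Near the apex the displacement profile
    is flat while the medial axis still ripples at the vertebra pitch, so
    the raw argmax can wander along the plateau; the vertex of a fit
    spanning a full ripple period localizes the apex far more stably. The
    fit falls back to the raw maximum for non-concave profiles (e.g. a
    monotone ramp, whose apex genuinely sits on the segment boundary).
    """
    sel = (disp.rows >= segment.start_row) & (disp.rows <= segment.end_row)
    if not sel.any():
        raise ValidationError("segment lies outside the displacement extent")
    rows, d = disp.rows[sel], disp.d[sel]
    i = int(np.argmax(np.abs(d)))  # argmax returns the first (smallest row)
    apex_row = float(rows[i])
    if refine:
        w = 0.2 * (segment.end_row - segment.start_row)
        wsel = np.abs(rows - apex_row) <= w
        if wsel.sum() >= 5:
            t = rows[wsel] - apex_row
            a, b, _c = np.polyfit(t, d[wsel], 2)
            # vertex only meaningful when curvature opposes the peak sign
            if abs(a) > 1e-12 and np.sign(a) == -np.sign(d[i]):
                apex_row += float(np.clip(-b / (2 * a), -w, w))
                apex_row = float(
                    np.clip(apex_row, segment.start_row, segment.end_row)
                )
    d_apex = float(np.interp(apex_row, rows, d))
    return apex_row, float(disp.csl_x + d_apex)


def _band_of(row: float, top_row: float, bottom_row: float) -> str:
    if not top_row <= row <= bottom_row:
        raise ValidationError(
            f"row {row} outside column extent [{top_row}, {bottom_row}]"
        )
    n = bottom_row - top_row + 1
    k = int((row - top_row) * len(VERTEBRA_NAMES) / n)
    return VERTEBRA_NAMES[min(k, len(VERTEBRA_NAMES) - 1)]


def label_vertebrae(
    landmarks: LandmarkSet, column_extent: tuple[float, float]
) -> LandmarkSet:
    """Assign nominal vertebral levels by an equal-height 17-band split.

    The column extent is divided into 17 equal bands named T1..T12, L1..L5
    and each landmark gets the band containing its row. This is bookkeeping
    for inter-rater agreement only — true vertebra heights vary, and no
    angle geometry depends on the labels.
    """
    top, bottom = column_extent
    labels = {
        "sev": _band_of(landmarks.sev[0], top, bottom),
        "av": _band_of(landmarks.av[0], top, bottom),
        "iev": _band_of(landmarks.iev[0], top, bottom),
    }
    return replace(landmarks, vertebra_labels=labels)


def full_extent_segment(disp: DisplacementSeries) -> CurveSegment:
    """Force a single segment over the whole displacement extent.

    Used to evaluate the angle methods on spines where no curve was
    detected (null measurements on straight columns). The apex is the row
    of maximal |d| within the middle half of the extent: an apex forced to
    the column's very ends would degenerate the apex-centered
    constructions, and on a flat displacement signal the global argmax is
    an arbitrary ripple row.
    """
    if len(disp) < 3:
        raise ValidationError("displacement series too short to force a segment")
    span = disp.rows[-1] - disp.rows[0]
    mid = (disp.rows >= disp.rows[0] + 0.25 * span) & (
        disp.rows <= disp.rows[-1] - 0.25 * span
    )
    idx = np.flatnonzero(mid)
    i = idx[int(np.argmax(np.abs(disp.d[idx])))]
    peak = float(disp.d[i])
    return CurveSegment(
        start_row=float(disp.rows[0]),
        apex_row=float(disp.rows[i]),
        end_row=float(disp.rows[-1]),
        direction=int(np.sign(peak)) or 1,
        max_displacement=abs(peak),
    )
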