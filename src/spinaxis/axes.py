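"""Medial axis (MA) and central sacral line (CSL) extraction.

The medial axis is the per-row midpoint of the column boundary's left and
right crossings — the automated stand-in for the curve through vertebral-body
centroids. The central sacral line is the vertical global-axis reference; the
signed per-row displacement between the two is the deformity signal that
drives landmark detection.

Coordinate convention: 0-based pixels, row 0 at the image top (superior),
x increasing rightward. Positive displacement means the MA lies to the right
of the CSL in image coordinates (patient side is not resolved; AP radiographs
are mirror-ambiguous without markers).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import Contour
from .errors import ColumnTooShortError, ValidationError

__all__ = [
    "MedialAxisSeries",
    "CentralSacralLine",
    "DisplacementSeries",
    "row_crossings",
    "medial_axis",
    "central_sacral_line",
    "displacement",
]

CSL_ANCHORS = ("bottom", "top", "mean")


@dataclass
class MedialAxisSeries:
    """Per-row medial-axis x-coordinates, rows strictly increasing."""

    rows: np.ndarray
    x: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.rows.shape != self.x.shape or self.rows.ndim != 1:
            raise ValidationError("rows and x must be 1-D arrays of equal length")
        if len(self.rows) == 0:
            raise ValidationError("medial axis is empty")
        if np.any(np.diff(self.rows) <= 0):
            raise ValidationError("rows must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def top_row(self) -> float:
        return float(self.rows[0])

    @property
    def bottom_row(self) -> float:
        return float(self.rows[-1])

    def x_at(self, row: float) -> float:
        """Linearly interpolated x at ``row`` (clamped to the extent)."""
        return float(np.interp(row, self.rows, self.x))


@dataclass
class CentralSacralLine:
    """Vertical reference line: a single column coordinate over a row span."""

    x: float
    top_row: float
    bottom_row: float

    def __post_init__(self):
        if not self.top_row < self.bottom_row:
            raise ValidationError("CSL requires top_row < bottom_row")


@dataclass
class DisplacementSeries:
    """Signed MA − CSL offsets per row; positive = MA right of CSL."""

    rows: np.ndarray
    d: np.ndarray
    csl_x: float

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.rows.shape != self.d.shape or self.rows.ndim != 1:
            raise ValidationError("rows and d must be 1-D arrays of equal length")
        if len(self.rows) == 0:
            raise ValidationError("displacement series is empty")

    def __len__(self) -> int:
        return len(self.rows)

    def ma_x(self) -> np.ndarray:
        """Recover MA x-coordinates (csl_x + d)."""
        return self.csl_x + self.d


def row_crossings(contour: Contour, row: int) -> tuple[int, int]:
    """Leftmost and rightmost contour columns at ``row``.

    When the contour crosses the row more than twice (concavities) the
    outermost pair is returned.
    """
    at = contour.points[contour.points[:, 0] == row]
    if len(at) == 0:
        raise ValidationError(f"no contour point at row {row}")
    return int(at[:, 1].min()), int(at[:, 1].max())


def medial_axis(contour: Contour, min_rows: int = 20) -> MedialAxisSeries:
    """Per-row midpoint of the outermost boundary crossings.

    Rows inside the contour's vertical extent with no contour point (possible
    after contour smoothing) are filled by linear interpolation between
    neighboring rows.
    """
    pts = contour.points
    rmin, rmax = int(pts[:, 0].min()), int(pts[:, 0].max())
    extent = rmax - rmin + 1
    if extent < min_rows:
        raise ColumnTooShortError(
            f"column spans {extent} rows (< {min_rows}): too short"
        )
    left = np.full(extent, np.inf)
    right = np.full(extent, -np.inf)
    idx = pts[:, 0] - rmin
    np.minimum.at(left, idx, pts[:, 1])
    np.maximum.at(right, idx, pts[:, 1])
    have = np.isfinite(left)
    mid = (left + right) / 2.0
    rows_all = np.arange(rmin, rmax + 1, dtype=float)
    x = np.interp(rows_all, rows_all[have], mid[have])
    return MedialAxisSeries(rows_all, x)


def central_sacral_line(
    ma: MedialAxisSeries, anchor: str = "bottom"
) -> CentralSacralLine:
    """Vertical CSL over the MA extent, anchored at the chosen MA sample.

    The clinical definition runs the line from the C1 center to S1, which
    over-determines a vertical line when those centers differ in x. The
    default anchors at the inferior (S1-end) sample; ``anchor`` may also be
    ``"top"`` or ``"mean"``.
    """
    if anchor not in CSL_ANCHORS:
        raise ValidationError(f"anchor must be one of {CSL_ANCHORS}")
    if anchor == "bottom":
        x = float(ma.x[-1])
    elif anchor == "top":
        x = float(ma.x[0])
    else:
        x = float(ma.x.mean())
    return CentralSacralLine(x=x, top_row=ma.top_row, bottom_row=ma.bottom_row)


def displacement(
    ma: MedialAxisSeries, csl: CentralSacralLine
) -> DisplacementSeries:
    """d(row) = MA x(row) − CSL x over the overlap of the two extents."""
    sel = (ma.rows >= csl.top_row) & (ma.rows <= csl.bottom_row)
    if not sel.any():
        raise ValidationError("MA and CSL extents do not overlap")
    return DisplacementSeries(ma.rows[sel], ma.x[sel] - csl.x, csl_x=csl.x)
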