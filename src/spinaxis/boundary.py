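"""Spinal-column boundary description.

The column envelope mask is reduced to a one-pixel (or ``radius``-pixel)
border band by morphological inner gradient, the largest connected border is
traced into an ordered closed contour (Moore-neighbor tracing), and the
contour coordinates can be smoothed with a circular Gaussian filter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import AnnihilationError, ValidationError

__all__ = [
    "Contour",
    "boundary_pixels",
    "select_largest_boundary",
    "smooth_boundary",
    "contour_to_mask",
]

# Moore neighborhood in clockwise order (image coordinates, row increases
# downward), starting at West. Order matters: the tracer scans clockwise
# from the backtrack direction.
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)],
    dtype=int,
)
_MOORE_INDEX = {tuple(d): i for i, d in enumerate(_MOORE)}


@dataclass
class Contour:
    """Ordered boundary contour in pixel coordinates.

    Attributes
    ----------
    points : ndarray of shape (N, 2)
        ``(row, col)`` integer coordinates, consecutive points 8-adjacent
        for traced contours.
    closed : bool
        Whether the last point neighbors the first.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("contour points must be an (N, 2) array")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


def _chebyshev_disc(radius: int) -> np.ndarray:
    """Square (2r+1)² structuring element (disc in the Chebyshev metric).

    Chosen over the Euclidean disc so that the radius-1 band coincides with
    the 8-neighbor border definition {p in mask : some 8-neighbor not in mask}.
    """
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def boundary_pixels(mask: np.ndarray, erosion_radius: int = 1) -> np.ndarray:
    """Inner morphological gradient: ``mask`` minus its erosion.

    Parameters
    ----------
    mask : 2-D bool array
        Non-empty object mask.
    erosion_radius : int
        Radius of the structuring element; the band is up to this many
        pixels thick along the object border.

    Returns
    -------
    2-D bool array of the border band.

    Raises
    ------
    ValidationError
        Empty mask or non-positive radius.
    AnnihilationError
        The erosion removed the object entirely.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise ValidationError("mask must be a non-empty 2-D binary array")
    if erosion_radius < 1:
        raise ValidationError("erosion_radius must be >= 1")
    eroded = ndimage.binary_erosion(
        mask, structure=_chebyshev_disc(erosion_radius), border_value=0
    )
    if not eroded.any():
        raise AnnihilationError(
            "erosion annihilates the mask (object thinner than the element)"
        )
    return mask & ~eroded


def _moore_trace(component: np.ndarray) -> np.ndarray:
    """Trace a connected component into a clockwise ordered pixel contour.

    Classic Moore-neighbor tracing with Jacob's stopping criterion: start at
    the topmost-then-leftmost pixel with the backtrack to its West (always
    exterior for that start), scan the Moore neighborhood clockwise from the
    backtrack, and stop when the start pixel is re-entered from the initial
    configuration.
    """
    pix = np.argwhere(component)  # row-major: first entry is topmost-leftmost
    start = tuple(pix[0])
    if len(pix) == 1:
        return pix.copy()

    contour = [start]
    current = start
    back = (start[0], start[1] - 1)
    initial = (current, back)
    max_steps = 4 * len(pix) + 8
    h, w = component.shape

    for _ in range(max_steps):
        d = _MOORE_INDEX[(back[0] - current[0], back[1] - current[1])]
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(d + k) % 8]
            r, c = current[0] + dr, current[1] + dc
            if 0 <= r < h and 0 <= c < w and component[r, c]:
                pr, pc = _MOORE[(d + k - 1) % 8]
                nxt = (r, c)
                back = (current[0] + pr, current[1] + pc)
                break
        if nxt is None:  # isolated pixel cluster exhausted
            break
        current = nxt
        if (current, back) == initial:
            break
        contour.append(current)
    return np.array(contour, dtype=int)


def select_largest_boundary(boundary_mask: np.ndarray) -> Contour:
    """Keep the largest connected border and trace it into a closed contour.

    Components are compared by pixel count; ties go to the component whose
    topmost-then-leftmost pixel comes first in raster order. Tracing is
    clockwise, starting from that pixel.
    """
    band = np.asarray(boundary_mask).astype(bool)
    if not band.any():
        raise ValidationError("boundary mask is empty")
    labels = measure.label(band, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) > 1:
        # raster order of each candidate's first pixel breaks the tie
        first_idx = {
            lab: np.flatnonzero(labels.ravel() == lab)[0] for lab in candidates
        }
        chosen = min(candidates, key=lambda lab: first_idx[lab])
    else:
        chosen = candidates[0]
    points = _moore_trace(labels == chosen)
    return Contour(points, closed=True)


def smooth_boundary(contour: Contour, sigma: float) -> Contour:
    """Circularly smooth contour coordinates with a Gaussian of ``sigma`` px.

    The row and column sequences are convolved independently (wrap mode, so
    the contour stays closed) and re-quantized to pixel coordinates;
    consecutive duplicates produced by re-quantization are dropped.
    ``sigma <= 0`` returns the contour unchanged.
    """
    if not contour.closed:
        raise ValidationError("smooth_boundary requires a closed contour")
    if len(contour) <= 8:
        raise ValidationError("contour too short to smooth (need > 8 points)")
    if sigma <= 0:
        return Contour(contour.points.copy(), closed=True)
    r = ndimage.gaussian_filter1d(contour.rows.astype(float), sigma, mode="wrap")
    c = ndimage.gaussian_filter1d(contour.cols.astype(float), sigma, mode="wrap")
    pts = np.stack([np.rint(r), np.rint(c)], axis=1).astype(int)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    if not keep.any():  # degenerate: everything collapsed to one pixel
        keep[0] = True
    return Contour(pts[keep], closed=True)


def contour_to_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize contour points back into a binary image of ``shape``."""
    mask = np.zeros(shape, dtype=bool)
    pts = contour.points
    inb = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
    )
    mask[pts[inb, 0], pts[inb, 1]] = True
    return mask
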