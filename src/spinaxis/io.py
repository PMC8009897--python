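"""Image and table IO.

Radiographs are read as 8-bit grayscale from PNG/TIFF (color inputs are
converted by luminance average, wider dtypes are min-max windowed to
[0, 255] with a logged warning). DICOM reading is available when pydicom
is installed.
"""
from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .axes import MedialAxisSeries
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "contour_to_csv", "axes_to_csv",
           "axes_from_csv"]


def _window_to_uint8(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as a 2-D uint8 grayscale array."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ValidationError(
                "reading DICOM requires the 'dicom' extra (pydicom)"
            ) from exc
        arr = pydicom.dcmread(path).pixel_array
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luminance average over color channels
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D grayscale image")
    if arr.dtype != np.uint8:
        log.warning("%s: windowing %s intensities to [0, 255]", path, arr.dtype)
        arr = _window_to_uint8(arr)
    return arr.astype(np.uint8)


def save_image(arr: np.ndarray, path: str | Path) -> None:
    """Write a 2-D array (bool masks become 0/255) as 8-bit PNG/TIFF."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr.astype(np.uint8))


def contour_to_csv(contour, path: str | Path) -> None:
    """Write a contour as index,row,col CSV."""
    df = pd.DataFrame(
        {
            "index": np.arange(len(contour)),
            "row": contour.rows,
            "col": contour.cols,
        }
    )
    df.to_csv(path, index=False)


def axes_to_csv(ma, csl, disp, path: str | Path) -> None:
    """Write the per-row MA/CSL/displacement table (row, ma_x, csl_x, d)."""
    df = pd.DataFrame(
        {"row": disp.rows, "ma_x": disp.csl_x + disp.d, "csl_x": disp.csl_x,
         "d": disp.d}
    )
    df.to_csv(path, index=False)


def axes_from_csv(path: str | Path):
    """Rebuild (MedialAxisSeries, csl_x) from an axes CSV."""
    from .axes import CentralSacralLine

    df = pd.read_csv(path)
    for col in ("row", "ma_x", "csl_x"):
        if col not in df.columns:
            raise ValidationError(f"axes CSV missing column {col!r}")
    ma = MedialAxisSeries(df["row"].to_numpy(), df["ma_x"].to_numpy())
    csl = CentralSacralLine(
        x=float(df["csl_x"].iloc[0]), top_row=ma.top_row, bottom_row=ma.bottom_row
    )
    return ma, csl
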