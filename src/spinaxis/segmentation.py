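"""Spinal-column extraction from the radiograph.

The bright vertebral column is separated from the darker thorax by an
optimum global threshold (the between-class-variance criterion), small disc
gaps are closed morphologically, the largest connected component is kept as
the column envelope, and the original intensities are restored under the
mask. A Fourier zero-padding resampler densifies/smooths 1-D profile series
downstream.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import resample
from skimage import measure
from skimage.morphology import disk

from .errors import ConstantImageError, NoColumnError, ValidationError

__all__ = [
    "optimum_global_threshold",
    "extract_spinal_column",
    "fft_interpolate",
]


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValidationError("image must be 2-D with height, width >= 2")
    if img.min() < 0 or img.max() > 255:
        raise ValidationError("intensities must lie in [0, 255]")
    return img.astype(np.uint8)


def optimum_global_threshold(image: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold over the 256-bin histogram.

    Returns the integer cut ``t``; foreground is ``image > t``. Ties are
    broken toward the lower threshold. Depends only on the histogram, so it
    is invariant to any spatial rearrangement of pixels, and adding a
    constant (within clipping range) shifts it by the same constant.

    Raises
    ------
    ConstantImageError
        If the image holds a single intensity (no threshold separates
        classes).
    """
    img = _check_image(image)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ConstantImageError("constant image: no threshold separates classes")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    omega = np.cumsum(p)  # class-0 weight for cut at t (inclusive)
    mu = np.cumsum(p * levels)
    mu_t = mu[-1]
    w0, w1 = omega[:-1], 1.0 - omega[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu[:-1]) ** 2 / (w0 * w1)
    sigma_b[(w0 <= 0) | (w1 <= 0)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximum


def extract_spinal_column(
    image: np.ndarray,
    closing_radius: int = 5,
    min_area: int = 500,
    max_foreground_fraction: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold, close disc gaps, keep the largest component, restore mask.

    Parameters
    ----------
    image : 2-D uint8 array
        AP radiograph.
    closing_radius : int
        Euclidean-disc radius of the morphological closing that merges
        vertebra blobs across intervertebral disc gaps into one column
        envelope.
    min_area : int
        Components smaller than this (in pixels) do not count as a column;
        guards against accepting noise speckle on column-free images.
    max_foreground_fraction : float
        If thresholding marks more than this fraction of the image as
        foreground, no bright minority structure exists (e.g. a pure-noise
        background split in half by the threshold) and no column is
        reported. The spinal column occupies a small minority of an AP
        radiograph.

    Returns
    -------
    mask : 2-D bool array
        The column envelope (largest foreground component after closing).
    masked : 2-D uint8 array
        Original intensities under the mask, zero elsewhere.
    """
    img = _check_image(image)
    t = optimum_global_threshold(img)
    fg = img > t
    frac = fg.mean()
    if frac > max_foreground_fraction:
        raise NoColumnError(
            f"no column found: foreground covers {frac:.0%} of the image "
            f"(> {max_foreground_fraction:.0%}); no bright minority structure"
        )
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(closing_radius))
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoColumnError("no column found: empty foreground")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    if counts[best] < min_area:
        raise NoColumnError(
            f"no column found: largest component has {counts[best]} px "
            f"(< {min_area})"
        )
    mask = labels == best
    masked = np.where(mask, img, 0).astype(np.uint8)
    return mask, masked


def fft_interpolate(series: np.ndarray, factor: int) -> np.ndarray:
    """Fourier (zero-padded-spectrum) resampling of a 1-D series.

    Resamples ``series`` to ``factor * len(series)`` points with amplitude
    preserved; band-limited inputs are reproduced exactly at the new sample
    positions. ``factor == 1`` returns a copy of the input.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 4:
        raise ValidationError("series must be 1-D with length >= 4")
    if int(factor) != factor or factor < 1:
        raise ValidationError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return s.copy()
    return resample(s, factor * len(s))
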