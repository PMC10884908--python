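"""Information volume map (IVM) and scalar image metrics.

The IVM turns a scanned image into a per-pixel object-likelihood map.  The
shading cast by the pattern sheet varies slowly across the image, while cells
and debris perturb brightness over a few pixels, so a Gaussian-blurred copy of
the scan serves as the background estimate and the blurred positive and
negative residuals carry the object signal:

    bg   = G_sigma_bg(img)
    ivm  = G_sigma_info(max(img - bg, 0)) + G_sigma_info(max(bg - img, 0))

with sigma_bg = 1.0 px and sigma_info = 1.5 px.  IVM values are tiny; they are
multiplied by 200 (display) or 100 (object contrast) and clipped at 1.0.

All Gaussian blurs use replicate (nearest) border handling and kernels
truncated at 4 sigma; the brute-force convolution oracle in the test suite
applies the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DISPLAY_GAIN = 200.0
CONTRAST_GAIN = 100.0
_TRUNCATE = 4.0


@dataclass
class ScanImage:
    """A grayscale scan: pixel values in [0, 1] plus the physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = 10.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class InfoVolumeMap:
    """Nonnegative object-likelihood map (pre-amplification)."""

    pixels: np.ndarray
    sigma_bg: float
    sigma_info: float
    source: ScanImage | None = field(default=None, repr=False)


def _pixels(img) -> np.ndarray:
    if isinstance(img, (ScanImage, InfoVolumeMap)):
        return img.pixels
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    return arr


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with replicate borders and 4-sigma kernel truncation."""
    return ndimage.gaussian_filter(
        np.asarray(img, dtype=float), sigma, mode="nearest", truncate=_TRUNCATE
    )


def compute_ivm(img, sigma_bg: float = 1.0, sigma_info: float = 1.5) -> InfoVolumeMap:
    """Information volume map of a scanned image.

    The background is the sigma_bg blur of the input; the positive and
    negative residuals are truncated at zero, blurred with sigma_info and
    summed.  Output is everywhere >= 0 and is invariant under intensity
    inversion (``c - img``) because the two residual maps swap.
    """
    if sigma_bg <= 0 or sigma_info <= 0:
        raise ValueError("sigmas must be positive")
    px = _pixels(img)
    bg = gaussian_blur(px, sigma_bg)
    pos = np.maximum(px - bg, 0.0)
    neg = np.maximum(bg - px, 0.0)
    # numerical guard: blurring a constant field leaves O(eps) residue that
    # would otherwise make the "no structure -> zero map" contract only
    # approximate
    tol = 16.0 * np.finfo(float).eps * max(1.0, float(np.abs(px).max()))
    pos[pos < tol] = 0.0
    neg[neg < tol] = 0.0
    out = gaussian_blur(pos, sigma_info) + gaussian_blur(neg, sigma_info)
    src = img if isinstance(img, ScanImage) else None
    return InfoVolumeMap(out, sigma_bg=sigma_bg, sigma_info=sigma_info, source=src)


def amplify_clip(ivm, factor: float) -> np.ndarray:
    """Multiply an IVM by ``factor`` and clip at 1.0 (pure white)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return np.minimum(_pixels(ivm) * factor, 1.0)


def object_contrast(ivm) -> float:
    """Variance of the x100-amplified IVM: object/background separability.

    Population variance (denominator N) over all pixels of
    ``amplify_clip(ivm, 100)``.
    """
    amp = amplify_clip(ivm, CONTRAST_GAIN)
    if np.ptp(amp) == 0:  # constant map: variance is exactly zero
        return 0.0
    return float(np.var(amp))


def brightness_stats(img) -> tuple[float, float]:
    """Mean and sample standard deviation (N-1) of all pixel values.

    The mean indexes overall image brightness, the deviation the spread of
    luminance introduced by the pattern sheet.  A single-pixel image has
    deviation 0 by definition.
    """
    px = _pixels(img)
    mean = float(np.mean(px))
    sd = 0.0 if px.size < 2 else float(np.std(px, ddof=1))
    return mean, sd


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def local_brightness_difference(img, radius_px: int = 10) -> np.ndarray:
    """Per-pixel max - min brightness over a disk neighborhood.

    The default 10-px radius matches the scale at which object visibility
    tracks shading steepness.  Borders are handled by replication.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    px = _pixels(img)
    fp = _disk_footprint(int(radius_px))
    mx = ndimage.maximum_filter(px, footprint=fp, mode="nearest")
    mn = ndimage.minimum_filter(px, footprint=fp, mode="nearest")
    return mx - mn


def cross_entropy(p, q, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of map ``q`` against reference map ``p``.

    Measures how hard it is to predict the cell-likelihood map on one side
    (e.g. the phase-derived cell region) from the other (the amplified IVM);
    identical maps minimize it (Gibbs' inequality).  ``q`` is clamped to
    [eps, 1-eps]; natural logarithm.
    """
    p = _pixels(p)
    q = _pixels(q)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.min() < 0 or p.max() > 1 or q.min() < 0 or q.max() > 1:
        raise ValueError("region maps must lie in [0, 1]")
    qc = np.clip(q, eps, 1.0 - eps)
    return float(np.mean(-(p * np.log(qc) + (1.0 - p) * np.log1p(-qc))))
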