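"""Rule-based cell detection on the amplified information volume map.

The production system behind this method uses a trained segmentation network
whose inference contract is simple: clear white IVM areas are cells, black is
background, gray is ambiguous.  This module is a pluggable rule-based
implementation of that contract: hysteresis thresholding (confident white
seeds grown into gray support), connected components, an area filter, and
distance-transform peak splitting for blobs too large to be a single cell.
Counts convert to densities via the physical pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .ivm import DISPLAY_GAIN, ScanImage, amplify_clip, compute_ivm, _pixels


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and size rules on the x200 display map.

    Defaults were calibrated once on the default synthetic scene; the white
    and gray levels encode the white-cell / black-background / ambiguous-gray
    reading of the amplified IVM.
    """

    white_thresh: float = 0.5
    gray_thresh: float = 0.2
    min_area_px: int = 4
    max_single_cell_area_px: int = 150
    split_min_distance_px: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.gray_thresh < self.white_thresh <= 1.0):
            raise ValueError("need 0 < gray_thresh < white_thresh <= 1")
        if self.min_area_px < 1 or self.max_single_cell_area_px < 1:
            raise ValueError("areas must be positive")
        if self.split_min_distance_px < 1:
            raise ValueError("split_min_distance_px must be >= 1")


@dataclass
class DetectionSet:
    """Detected cell centroids (row, col) and component areas in px."""

    centroids: np.ndarray
    areas_px: np.ndarray
    source: str = ""
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float).reshape(-1, 2)
        self.areas_px = np.asarray(self.areas_px, int).reshape(-1)
        if len(self.centroids) != len(self.areas_px):
            raise ValueError("one area per centroid required")

    def __len__(self) -> int:
        return len(self.centroids)


def _edt_split(comp_mask: np.ndarray, cfg: DetectorConfig):
    """Split an oversized component at its distance-transform maxima."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndimage.distance_transform_edt(comp_mask)
    peaks = peak_local_max(
        dist,
        min_distance=cfg.split_min_distance_px,
        labels=comp_mask,
        exclude_border=False,
    )
    if len(peaks) < 2:
        return [comp_mask]
    markers = np.zeros(comp_mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=comp_mask)
    return [labels == i for i in range(1, len(peaks) + 1)]


def _peak_split(comp_mask: np.ndarray, intensity: np.ndarray,
                cfg: DetectorConfig):
    """Split a component at separated intensity peaks of the unclipped IVM."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    peaks = peak_local_max(
        intensity,
        min_distance=cfg.split_min_distance_px,
        threshold_abs=cfg.white_thresh,
        labels=comp_mask.astype(int),
        exclude_border=False,
    )
    if len(peaks) < 2:
        return None
    markers = np.zeros(comp_mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-intensity, markers, mask=comp_mask)
    return [labels == i for i in range(1, len(peaks) + 1)]


def detect_cells(
    ivm_display, cfg: DetectorConfig | None = None, intensity=None
) -> DetectionSet:
    """Detect cells on an amplified IVM display map (values in [0, 1]).

    Seeds at >= ``white_thresh`` are grown into their connected
    >= ``gray_thresh`` support (hysteresis); components below
    ``min_area_px`` are dropped and components above
    ``max_single_cell_area_px`` are split at distance-transform peaks at
    least ``split_min_distance_px`` apart.  When the *unclipped* amplified
    IVM is supplied as ``intensity`` (as :func:`detect_scan` does),
    components holding two or more separated intensity peaks at white level
    are split at those peaks instead — the display map saturates over cell
    cores, so nearby cells that merge into one clipped plateau stay
    separable on the unclipped map.  Centroids are intensity-weighted.
    Deterministic.
    """
    cfg = cfg or DetectorConfig()
    img = _pixels(ivm_display)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("display map must lie in [0, 1]")
    inten = None if intensity is None else np.asarray(intensity, float)
    if inten is not None and inten.shape != img.shape:
        raise ValueError("intensity map must match display shape")

    from skimage.filters import apply_hysteresis_threshold

    grown = apply_hysteresis_threshold(img, cfg.gray_thresh, cfg.white_thresh)
    labels, n = ndimage.label(grown, structure=np.ones((3, 3), dtype=int))
    centroids, areas = [], []
    if n:
        objects = ndimage.find_objects(labels)
        for idx, sl in enumerate(objects, start=1):
            comp = labels[sl] == idx
            area = int(comp.sum())
            if area < cfg.min_area_px:
                continue
            weight_src = img[sl] if inten is None else inten[sl]
            parts = None
            if inten is not None:
                parts = _peak_split(comp, inten[sl], cfg)
            if parts is None:
                parts = (
                    _edt_split(comp, cfg)
                    if area > cfg.max_single_cell_area_px
                    else [comp]
                )
            off = np.array([sl[0].start, sl[1].start], dtype=float)
            for part in parts:
                a = int(part.sum())
                if a < 1:
                    continue
                rows, cols = np.nonzero(part)
                w = np.maximum(weight_src[rows, cols] - cfg.gray_thresh, 1e-9)
                w = w * w
                centroids.append(
                    off + [np.average(rows, weights=w),
                           np.average(cols, weights=w)]
                )
                areas.append(a)
    return DetectionSet(
        np.asarray(centroids, float).reshape(-1, 2),
        np.asarray(areas, int),
        config=asdict(cfg),
    )


def cell_density(count: int, area_px: int, pixel_size_um: float) -> float:
    """Cells per cm^2 from a count over an area of ``area_px`` pixels."""
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    area_cm2 = area_px * (pixel_size_um * 1e-4) ** 2
    return count / area_cm2


_PAD_PX = 16


def _pad_linear(img: np.ndarray, n: int) -> np.ndarray:
    """Extend an image by first-order extrapolation of its edge slope.

    The analysis window is a crop of a physically larger scan; replicate
    padding would put an artificial slope break at the window edge and the
    background-subtraction step would light it up as a line of false
    objects.  Linear extrapolation continues the smooth shading instead.
    The edge value and slope come from a lightly smoothed copy of the image
    so pixel noise at the border is not amplified into the pad.
    """
    from .ivm import gaussian_blur

    sm = gaussian_blur(img, 2.0)
    kl = np.arange(n, 0, -1, dtype=float)
    kr = np.arange(1, n + 1, dtype=float)
    left = sm[:, [0]] + (sm[:, [0]] - sm[:, [1]]) * kl
    right = sm[:, [-1]] + (sm[:, [-1]] - sm[:, [-2]]) * kr
    out = np.hstack([left, img, right])
    sm2 = np.hstack([left, sm, right])
    top = sm2[[0], :] + (sm2[[0], :] - sm2[[1], :]) * kl[:, None]
    bottom = sm2[[-1], :] + (sm2[[-1], :] - sm2[[-2], :]) * kr[:, None]
    return np.vstack([top, out, bottom])


def detect_scan(scan, cfg: DetectorConfig | None = None) -> DetectionSet:
    """Full single-field pipeline: scan -> IVM -> x200 display -> detections.

    The scan is linearly edge-extrapolated before the IVM so the window
    border casts no spurious objects, and the unclipped amplified IVM is
    passed alongside the display map so merged neighbouring cells can be
    split at their intensity peaks.
    """
    px = scan.pixels if isinstance(scan, ScanImage) else np.asarray(scan, float)
    pad = min(_PAD_PX, min(px.shape) - 1)
    ivm = compute_ivm(_pad_linear(px, pad))
    core = (slice(pad, pad + px.shape[0]), slice(pad, pad + px.shape[1]))
    display = amplify_clip(ivm, DISPLAY_GAIN)[core]
    return detect_cells(
        display, cfg, intensity=(ivm.pixels * DISPLAY_GAIN)[core]
    )


def count_whole_vessel(
    scan,
    vessel_mask: np.ndarray | None = None,
    cfg: DetectorConfig | None = None,
    tile_px: int = 512,
    overlap_px: int = 64,
) -> DetectionSet:
    """Tile a whole-vessel scan, detect per tile, and count seam cells once.

    Tiles partition the masked area into non-overlapping *core* rectangles;
    each tile is processed with ``overlap_px`` of surrounding context, and a
    detection is kept only when its centroid lies in the tile's own core, so
    every location is counted by exactly one tile.
    """
    px = scan.pixels if isinstance(scan, ScanImage) else np.asarray(scan, float)
    h, w = px.shape
    if vessel_mask is None:
        vessel_mask = np.ones((h, w), dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != px.shape:
        raise ValueError("vessel mask must match scan shape")
    if not vessel_mask.any():
        warnings.warn("empty vessel mask: count is 0", stacklevel=2)
        return DetectionSet(np.empty((0, 2)), np.empty(0, dtype=int))

    cfg = cfg or DetectorConfig()
    centroids, areas = [], []
    for r0 in range(0, h, tile_px):
        for c0 in range(0, w, tile_px):
            r1, c1 = min(r0 + tile_px, h), min(c0 + tile_px, w)
            er0, ec0 = max(0, r0 - overlap_px), max(0, c0 - overlap_px)
            er1, ec1 = min(h, r1 + overlap_px), min(w, c1 + overlap_px)
            det = detect_scan(px[er0:er1, ec0:ec1], cfg)
            for (r, c), a in zip(det.centroids, det.areas_px):
                gr, gc = r + er0, c + ec0
                if not (r0 <= gr < r1 and c0 <= gc < c1):
                    continue  # another tile owns this location
                ir, ic = int(round(gr)), int(round(gc))
                if vessel_mask[min(ir, h - 1), min(ic, w - 1)]:
                    centroids.append((gr, gc))
                    areas.append(a)
    return DetectionSet(
        np.asarray(centroids, float).reshape(-1, 2),
        np.asarray(areas, int),
        config=asdict(cfg),
    )
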