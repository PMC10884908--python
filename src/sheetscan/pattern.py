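"""Hole-pattern geometry for pattern sheets.

A pattern sheet is an opaque film perforated by circular holes on a regular
lattice.  Placed between the scanner's light source and the culture vessel it
casts a shading pattern whose black-white transitions make refractive cells
visible.  Cells are visible only inside a *visualization band* of empirically
~680 um total width centered on each open/closed boundary, so the fraction of
sheet area lying within 340 um of a boundary (the *coverage ratio*) is the
selection criterion between hole sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: hole diameters (um) of the four manufactured sheets compared in practice
STANDARD_HOLE_DIAMETERS_UM = (280.0, 450.0, 700.0, 850.0)

#: half-width (um) of the visualization band around each hole boundary
DEFAULT_HALF_WIDTH_UM = 340.0


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of a perforated pattern sheet.

    Parameters
    ----------
    hole_diameter_um:
        Diameter of the circular holes.  280/450/700/850 um are the
        manufactured sizes; any positive value is accepted.
    pitch_um:
        Center-to-center spacing of holes along a lattice axis.  Must be at
        least the hole diameter so holes never overlap.
    lattice:
        ``"square"`` or ``"hex"`` arrangement of hole centers.
    sheet_width_um, sheet_height_um:
        Physical extent of the sheet.
    """

    hole_diameter_um: float = 450.0
    pitch_um: float = 900.0
    lattice: str = "square"
    sheet_width_um: float = 10_000.0
    sheet_height_um: float = 10_000.0

    def __post_init__(self) -> None:
        if self.hole_diameter_um <= 0:
            raise ValueError("hole_diameter_um must be positive")
        if self.pitch_um < self.hole_diameter_um:
            raise ValueError(
                "pitch_um must be >= hole_diameter_um (non-overlapping holes)"
            )
        if self.lattice not in ("square", "hex"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if min(self.sheet_width_um, self.sheet_height_um) <= self.pitch_um:
            raise ValueError("sheet must be larger than one pitch")


def hole_centers(spec: PatternSpec) -> np.ndarray:
    """Hole centers in um as an (n, 2) array of (y, x), sheet origin top-left.

    The lattice is centered on the sheet.  For the hex lattice rows are spaced
    ``pitch * sqrt(3)/2`` apart with alternate rows offset by half a pitch,
    giving ``2/sqrt(3)`` times the areal hole density of the square lattice at
    equal pitch.
    """
    w, h, p = spec.sheet_width_um, spec.sheet_height_um, spec.pitch_um
    cy, cx = h / 2.0, w / 2.0
    centers = []
    if spec.lattice == "square":
        row_pitch = p
        ny = int(math.floor(h / row_pitch)) + 2
        nx = int(math.floor(w / p)) + 2
        for iy in range(-ny, ny + 1):
            y = cy + iy * row_pitch
            for ix in range(-nx, nx + 1):
                x = cx + ix * p
                centers.append((y, x))
    else:  # hex
        row_pitch = p * math.sqrt(3.0) / 2.0
        ny = int(math.floor(h / row_pitch)) + 2
        nx = int(math.floor(w / p)) + 2
        for iy in range(-ny, ny + 1):
            y = cy + iy * row_pitch
            off = (p / 2.0) if (iy % 2) else 0.0
            for ix in range(-nx, nx + 1):
                x = cx + ix * p + off
                centers.append((y, x))
    arr = np.asarray(centers, dtype=float)
    r = spec.hole_diameter_um / 2.0
    # keep holes that intersect the sheet at all
    keep = (
        (arr[:, 0] > -r)
        & (arr[:, 0] < h + r)
        & (arr[:, 1] > -r)
        & (arr[:, 1] < w + r)
    )
    return arr[keep]


def rasterize_pattern(spec: PatternSpec, px_um: float) -> np.ndarray:
    """Rasterize a pattern sheet; True marks open (hole) pixels.

    ``px_um`` must be at most ``hole_diameter_um / 4`` so each hole spans at
    least 4 pixels across.  Pixel (i, j) samples the sheet at its center,
    ``((i + 0.5) * px_um, (j + 0.5) * px_um)``.
    """
    if px_um <= 0:
        raise ValueError("px_um must be positive")
    if px_um > spec.hole_diameter_um / 4.0:
        raise ValueError(
            f"px_um={px_um} too coarse for {spec.hole_diameter_um} um holes "
            "(need px_um <= hole_diameter_um / 4)"
        )
    ny = int(round(spec.sheet_height_um / px_um))
    nx = int(round(spec.sheet_width_um / px_um))
    mask = np.zeros((ny, nx), dtype=bool)
    r = spec.hole_diameter_um / 2.0
    yy = (np.arange(ny) + 0.5) * px_um
    xx = (np.arange(nx) + 0.5) * px_um
    for cy, cx in hole_centers(spec):
        iy0 = max(0, int((cy - r) / px_um) - 1)
        iy1 = min(ny, int((cy + r) / px_um) + 2)
        ix0 = max(0, int((cx - r) / px_um) - 1)
        ix1 = min(nx, int((cx + r) / px_um) + 2)
        if iy0 >= iy1 or ix0 >= ix1:
            continue
        dy = yy[iy0:iy1, None] - cy
        dx = xx[None, ix0:ix1] - cx
        mask[iy0:iy1, ix0:ix1] |= dy * dy + dx * dx <= r * r
    return mask


def boundary_distance_um(mask: np.ndarray, px_um: float) -> np.ndarray:
    """Per-pixel Euclidean distance (um) to the open/closed interface.

    Computed as the one-sided distance transform on each side of the
    interface minus half a pixel, which places the interface between the
    open and closed pixel layers to sub-pixel accuracy.  Returns +inf when
    the mask has no interface (all open or all closed).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or (~mask).all():
        return np.full(mask.shape, np.inf)
    d_open = ndimage.distance_transform_edt(mask)  # distance to nearest closed
    d_closed = ndimage.distance_transform_edt(~mask)
    dist_px = np.where(mask, d_open, d_closed) - 0.5
    return np.maximum(dist_px, 0.0) * px_um


def coverage_ratio(
    mask: np.ndarray,
    half_width_um: float = DEFAULT_HALF_WIDTH_UM,
    px_um: float = 10.0,
) -> float:
    """Fraction of sheet area within ``half_width_um`` of a hole boundary.

    This is the geometric *coverage ratio* used to rank hole sizes: pixels on
    either side of an open/closed interface whose distance to the interface is
    at most the visualization-band half-width count as covered.  A mask with
    no boundary at all (solid or fully open sheet) has zero coverage and
    triggers a warning.
    """
    if half_width_um <= 0:
        raise ValueError("half_width_um must be positive")
    mask = np.asarray(mask, dtype=bool)
    dist = boundary_distance_um(mask, px_um)
    if np.isinf(dist).all():
        warnings.warn("mask has no open/closed boundary; coverage is 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean(dist <= half_width_um))


def coverage_sweep(
    diameters_um=STANDARD_HOLE_DIAMETERS_UM,
    pitch_rule=lambda d: 2.0 * d,
    px_um: float = 10.0,
    half_width_um: float = DEFAULT_HALF_WIDTH_UM,
    lattice: str = "square",
    sheet_width_um: float = 10_000.0,
    sheet_height_um: float = 10_000.0,
):
    """Coverage ratio for each hole diameter under a pitch rule.

    Returns a ``pandas.DataFrame`` with columns ``hole_diameter_um``,
    ``pitch_um`` and ``coverage`` sorted by diameter; the row index of the
    maximum coverage is exposed through ``df.attrs["argmax_diameter_um"]``.
    The ranking depends on the pitch rule and lattice, which are free inputs:
    manufactured sheets do not publish their layouts.
    """
    import pandas as pd

    rows = []
    for d in sorted(diameters_um):
        spec = PatternSpec(
            hole_diameter_um=d,
            pitch_um=float(pitch_rule(d)),
            lattice=lattice,
            sheet_width_um=sheet_width_um,
            sheet_height_um=sheet_height_um,
        )
        mask = rasterize_pattern(spec, px_um)
        cov = coverage_ratio(mask, half_width_um, px_um)
        rows.append(
            {"hole_diameter_um": d, "pitch_um": spec.pitch_um, "coverage": cov}
        )
    df = pd.DataFrame(rows).sort_values("hole_diameter_um", ignore_index=True)
    df.attrs["argmax_diameter_um"] = float(
        df.loc[df["coverage"].idxmax(), "hole_diameter_um"]
    )
    return df
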