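"""Field-of-view sampling bias: estimating a whole-vessel count from k fields.

Microscopes see only small fields of view; the whole-vessel count is commonly
estimated by averaging a handful of microscope-sized fields and scaling by
area.  This module places 25 such fields (a 5x5 grid of 640x480-px rectangles
at 10 um/px by default) inside a vessel mask, forms the scaled-mean estimator
from k of them, and reports the percent discrepancy against the true total —
per subset, per time-lapse frame, and summarized as max/min/mean per k.

The estimator is unbiased over subsets by linearity; its subset-to-subset
variance shrinks with the finite-population correction
``(1/k) * (N - k)/(N - 1)`` for N = 25 fields, so single-field estimates are
far noisier than 20-field ones, and relative spread grows as counts fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FIELD_W_PX = 640
DEFAULT_FIELD_H_PX = 480
DEFAULT_KS = (1, 3, 5, 10, 20)
DEFAULT_N_COMBOS = 5


@dataclass
class FieldGrid:
    """n_side x n_side microscope-sized fields placed inside a vessel."""

    rects: np.ndarray  # (n, 4) int: row0, col0, row1, col1 (half-open)
    pixel_size_um: float
    vessel_area_px: int

    @property
    def n_fields(self) -> int:
        return len(self.rects)

    @property
    def field_area_px(self) -> int:
        r0, c0, r1, c1 = self.rects[0]
        return int((r1 - r0) * (c1 - c0))

    @property
    def field_area_cm2(self) -> float:
        return self.field_area_px * (self.pixel_size_um * 1e-4) ** 2

    @property
    def vessel_area_cm2(self) -> float:
        return self.vessel_area_px * (self.pixel_size_um * 1e-4) ** 2


def _inscribed_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """A large axis-aligned box inside the mask, grown from its centroid."""
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("vessel mask is empty")
    cr, cc = rows.mean(), cols.mean()
    h, w = mask.shape
    hr_max = min(cr, h - 1 - cr)
    hc_max = min(cc, w - 1 - cc)

    def fits(s: float) -> bool:
        r0, r1 = int(cr - s * hr_max), int(cr + s * hr_max)
        c0, c1 = int(cc - s * hc_max), int(cc + s * hc_max)
        if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
            return False
        sub = mask[r0 : r1 + 1, c0 : c1 + 1]
        return bool(sub.all())

    lo, hi = 0.0, 1.0
    if fits(1.0):
        lo = 1.0
    else:
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if fits(mid):
                lo = mid
            else:
                hi = mid
    s = lo
    return (
        int(cr - s * hr_max), int(cc - s * hc_max),
        int(cr + s * hr_max), int(cc + s * hc_max),
    )


def place_fields(
    vessel_mask: np.ndarray,
    field_w_px: int = DEFAULT_FIELD_W_PX,
    field_h_px: int = DEFAULT_FIELD_H_PX,
    n_side: int = 5,
    pixel_size_um: float = 10.0,
) -> FieldGrid:
    """Center ``n_side**2`` non-overlapping fields on a regular grid.

    Field centers are spaced evenly over the largest centered box inscribed
    in the vessel mask; raises when the fields cannot fit without overlap or
    would protrude from the vessel.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    r0, c0, r1, c1 = _inscribed_box(mask)
    ch = np.linspace(r0 + field_h_px / 2, r1 - field_h_px / 2, n_side)
    cw = np.linspace(c0 + field_w_px / 2, c1 - field_w_px / 2, n_side)
    if n_side > 1 and (
        ch[1] - ch[0] < field_h_px or cw[1] - cw[0] < field_w_px
    ):
        raise ValueError(
            f"{n_side}x{n_side} grid of {field_w_px}x{field_h_px}-px fields "
            "does not fit the vessel without overlap"
        )
    rects = []
    for y in ch:
        for x in cw:
            rr0 = int(round(y - field_h_px / 2))
            cc0 = int(round(x - field_w_px / 2))
            rr1, cc1 = rr0 + field_h_px, cc0 + field_w_px
            if not mask[rr0:rr1, cc0:cc1].all():
                raise ValueError("a field protrudes beyond the vessel mask")
            rects.append((rr0, cc0, rr1, cc1))
    return FieldGrid(
        rects=np.asarray(rects, int),
        pixel_size_um=pixel_size_um,
        vessel_area_px=int(mask.sum()),
    )


def field_counts(centroids: np.ndarray, grid: FieldGrid) -> np.ndarray:
    """Number of centroids inside each field rectangle."""
    pts = np.asarray(centroids, float).reshape(-1, 2)
    out = np.zeros(grid.n_fields, dtype=int)
    for i, (r0, c0, r1, c1) in enumerate(grid.rects):
        if len(pts):
            inside = (
                (pts[:, 0] >= r0) & (pts[:, 0] < r1)
                & (pts[:, 1] >= c0) & (pts[:, 1] < c1)
            )
            out[i] = int(inside.sum())
    return out


def estimate_from_fields(
    counts: np.ndarray,
    grid: FieldGrid,
    k: int,
    true_total: float,
    n_combos: int = DEFAULT_N_COMBOS,
    rng: np.random.Generator | None = None,
    frame: int = 0,
    combos: list | None = None,
) -> pd.DataFrame:
    """Scaled-mean whole-vessel estimates from k-field subsets.

    estimate = mean(count over the k sampled fields) / field_area x
    vessel_area.  For k = 1 all singleton fields are reported; otherwise
    ``n_combos`` subsets are drawn without replacement (or taken from
    ``combos`` when the caller fixes them across frames).  Discrepancy is
    100 x (estimate - true) / true.
    """
    counts = np.asarray(counts)
    nf = grid.n_fields
    if counts.shape != (nf,):
        raise ValueError(f"need one count per field ({nf})")
    if not (1 <= k <= nf):
        raise ValueError(f"k must be in [1, {nf}]")
    if true_total <= 0:
        raise ValueError("true_total must be positive")
    if combos is None:
        if k == 1:
            combos = [np.array([i]) for i in range(nf)]
        else:
            if rng is None:
                raise ValueError("rng required when combos are drawn")
            combos = [rng.choice(nf, size=k, replace=False)
                      for _ in range(n_combos)]
    scale = grid.vessel_area_cm2 / grid.field_area_cm2
    rows = []
    for ci, combo in enumerate(combos):
        est = counts[np.asarray(combo)].mean() * scale
        rows.append(
            {
                "frame": frame,
                "k": k,
                "combo": ci,
                "estimated_total": est,
                "true_total": float(true_total),
                "discrepancy_pct": 100.0 * (est - true_total) / true_total,
            }
        )
    return pd.DataFrame(rows)


def timeseries_discrepancy(
    per_frame_counts,
    per_frame_totals,
    grid: FieldGrid,
    ks=DEFAULT_KS,
    n_combos: int = DEFAULT_N_COMBOS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-frame k-field discrepancies with field positions fixed over time.

    The k-field subsets are drawn once per k and reused for every frame, so
    each reported line is the time series of one fixed set of observation
    points.
    """
    rng = rng or np.random.default_rng(0)
    per_frame_counts = [np.asarray(c) for c in per_frame_counts]
    if len(per_frame_counts) != len(per_frame_totals):
        raise ValueError("need one true total per frame")
    nf = grid.n_fields
    for c in per_frame_counts:
        if c.shape != (nf,):
            raise ValueError("inconsistent per-frame field counts")
    combos_by_k = {}
    for k in ks:
        if k == 1:
            combos_by_k[k] = [np.array([i]) for i in range(nf)]
        else:
            combos_by_k[k] = [
                rng.choice(nf, size=k, replace=False) for _ in range(n_combos)
            ]
    frames = []
    for f, (counts, total) in enumerate(zip(per_frame_counts, per_frame_totals)):
        for k in ks:
            frames.append(
                estimate_from_fields(
                    counts, grid, k, total, frame=f, combos=combos_by_k[k]
                )
            )
    return pd.concat(frames, ignore_index=True)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Max/min/mean discrepancy per (frame, k)."""
    return (
        results.groupby(["frame", "k"])["discrepancy_pct"]
        .agg(["max", "min", "mean"])
        .reset_index()
    )
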