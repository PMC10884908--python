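"""Detection-vs-truth matching and the four-way counting-error taxonomy.

Over-detections split into *image-origin* errors (debris or detached cells
picked up as cells) and *large-cell* errors (one oversized cell reported as
two detections).  Under-detections split into *blind spots* (cells hidden in
the dark zones of the shading pattern) and *lack of resolution* (cells missed
in densely populated areas).  Every unmatched detection or truth point is
assigned to exactly one category or left unclassified, and the report's
accounting identities hold on every run:

    matched + over_* + unclassified_over  == n_detected
    matched + under_* + unclassified_under == n_truth
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MATCH_RADIUS_PX = 5.0  # ~50 um at scanner resolution
LARGE_CELL_MIN_DIAMETER_UM = 25.0  # above the 15-20 um culture range


@dataclass
class Matching:
    """One-to-one greedy matching between detections and truth points."""

    pairs: list[tuple[int, int]]  # (truth_idx, det_idx)
    unmatched_truth: list[int]
    unmatched_det: list[int]
    max_dist_px: float


@dataclass
class ErrorReport:
    n_truth: int
    n_detected: int
    matched: int
    over_image_origin: int
    over_large_cell: int
    under_blind_spot: int
    under_resolution: int
    unclassified_over: int
    unclassified_under: int

    def __post_init__(self) -> None:
        over = (self.over_image_origin + self.over_large_cell
                + self.unclassified_over)
        under = (self.under_blind_spot + self.under_resolution
                 + self.unclassified_under)
        if self.matched + over != self.n_detected:
            raise ValueError("over-detection accounting identity violated")
        if self.matched + under != self.n_truth:
            raise ValueError("under-detection accounting identity violated")

    def percentages(self) -> dict[str, float]:
        """Each category as 100 x count / n_truth."""
        if self.n_truth == 0:
            raise ValueError("percentages undefined with zero truth objects")
        f = 100.0 / self.n_truth
        return {
            "over_image_origin_pct": self.over_image_origin * f,
            "over_large_cell_pct": self.over_large_cell * f,
            "under_blind_spot_pct": self.under_blind_spot * f,
            "under_resolution_pct": self.under_resolution * f,
        }


def match_detections(det, truth, max_dist_px: float = DEFAULT_MATCH_RADIUS_PX):
    """Greedy one-to-one matching by ascending pairwise distance.

    Candidate pairs within ``max_dist_px`` are sorted by (distance,
    truth index, detection index) and accepted greedily; ties therefore
    resolve toward the lower truth index.  ``det`` and ``truth`` may be
    DetectionSet/TruthSet objects or plain (n, 2) centroid arrays.
    """
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be positive")
    dpts = np.asarray(getattr(det, "centroids", det), float).reshape(-1, 2)
    tpts = np.asarray(getattr(truth, "cell_centroids", truth), float).reshape(-1, 2)
    if len(dpts) == 0 or len(tpts) == 0:
        return Matching([], list(range(len(tpts))), list(range(len(dpts))),
                        max_dist_px)
    dist = np.linalg.norm(tpts[:, None, :] - dpts[None, :, :], axis=2)
    ti, di = np.nonzero(dist <= max_dist_px)
    order = np.lexsort((di, ti, dist[ti, di]))
    used_t, used_d, pairs = set(), set(), []
    for k in order:
        t, d = int(ti[k]), int(di[k])
        if t in used_t or d in used_d:
            continue
        pairs.append((t, d))
        used_t.add(t)
        used_d.add(d)
    unmatched_t = [i for i in range(len(tpts)) if i not in used_t]
    unmatched_d = [i for i in range(len(dpts)) if i not in used_d]
    return Matching(pairs, unmatched_t, unmatched_d, max_dist_px)


def classify_errors(
    matching: Matching,
    det,
    truth,
    debris_radius_px: float = DEFAULT_MATCH_RADIUS_PX,
    large_cell_min_diameter_um: float = LARGE_CELL_MIN_DIAMETER_UM,
    pixel_size_um: float = 10.0,
    crowd_radius_px: float | None = None,
) -> ErrorReport:
    """Classify unmatched detections and truths into the four error classes.

    Rules (precedence: image-origin > large-cell, blind-spot > resolution):

    * unmatched detection within ``debris_radius_px`` of a debris centroid
      -> image-origin over-detection;
    * else, unmatched detection whose nearest truth (within the matching
      radius) is a matched *large* cell -> large-cell over-detection
      (one big cell split into two reports);
    * unmatched truth lying inside the dark-zone mask -> blind spot;
    * else, unmatched truth with another truth within the crowd radius
      (default 2 x median cell diameter in px) -> lack of resolution.

    ``truth`` must supply debris centroids, the dark-zone mask and cell
    diameters; a missing layer raises with the classification it disables.
    """
    dpts = np.asarray(getattr(det, "centroids", det), float).reshape(-1, 2)
    tpts = np.asarray(truth.cell_centroids, float).reshape(-1, 2)
    debris = getattr(truth, "debris_centroids", None)
    dark = getattr(truth, "dark_zone_mask", None)
    diam = getattr(truth, "cell_diameters_um", None)
    missing = [
        name
        for name, layer in [
            ("debris_centroids (image-origin class)", debris),
            ("dark_zone_mask (blind-spot class)", dark),
            ("cell_diameters_um (large-cell and resolution classes)", diam),
        ]
        if layer is None
    ]
    if missing:
        raise ValueError("missing aux layers: " + "; ".join(missing))
    debris = np.asarray(debris, float).reshape(-1, 2)
    diam = np.asarray(diam, float)

    if crowd_radius_px is None:
        med_d_px = np.median(diam) / pixel_size_um if len(diam) else 0.0
        crowd_radius_px = 2.0 * med_d_px

    matched_truths = {t for t, _ in matching.pairs}
    over_img = over_large = uncls_over = 0
    for d in matching.unmatched_det:
        p = dpts[d]
        if len(debris) and np.min(np.linalg.norm(debris - p, axis=1)) <= debris_radius_px:
            over_img += 1
            continue
        if len(tpts):
            dists = np.linalg.norm(tpts - p, axis=1)
            t = int(np.argmin(dists))
            if (
                dists[t] <= matching.max_dist_px
                and t in matched_truths
                and diam[t] >= large_cell_min_diameter_um
            ):
                over_large += 1
                continue
        uncls_over += 1

    blind = resol = uncls_under = 0
    for t in matching.unmatched_truth:
        r, c = int(round(tpts[t, 0])), int(round(tpts[t, 1]))
        r = min(max(r, 0), dark.shape[0] - 1)
        c = min(max(c, 0), dark.shape[1] - 1)
        if dark[r, c]:
            blind += 1
            continue
        others = np.linalg.norm(tpts - tpts[t], axis=1)
        others[t] = np.inf
        if len(tpts) > 1 and others.min() <= crowd_radius_px:
            resol += 1
        else:
            uncls_under += 1

    return ErrorReport(
        n_truth=len(tpts),
        n_detected=len(dpts),
        matched=len(matching.pairs),
        over_image_origin=over_img,
        over_large_cell=over_large,
        under_blind_spot=blind,
        under_resolution=resol,
        unclassified_over=uncls_over,
        unclassified_under=uncls_under,
    )


def accuracy_by_density(det_density: float, truth_density: float) -> float:
    """Percent error of a detected density against the reference density."""
    if truth_density <= 0:
        raise ValueError("truth_density must be positive")
    return 100.0 * abs(det_density - truth_density) / truth_density


def r_squared(x, y) -> float:
    """Squared Pearson correlation of paired samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
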