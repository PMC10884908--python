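"""Seeded synthetic scan/phase/nuclei scene generator with full ground truth.

Emulates what a flatbed scanner sees through a perforated pattern sheet: a
slowly varying shading field with ~680-um-wide black-white transition bands,
cells that appear as tiny zero-mean brightness dipoles whose visibility scales
with the local shading gradient, debris that shows up in the scan and phase
images but not in the nuclei channel, and additive Gaussian sensor noise.
The paired phase image carries small bright blobs at each cell (a stand-in
for phase-contrast halos at scanner resolution) and the nuclei image carries
tight Gaussian spots, so segmentation, detection and error-taxonomy code can
all be scored against exact ground truth.

Every scene is a pure function of its :class:`SceneParams` (including the
seed): identical parameters give bit-identical pixel arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .pattern import PatternSpec, rasterize_pattern

# 10-90% width of an error function equals 2*1.28155*sigma; a 680 um wide
# transition band across a straight open/closed boundary therefore needs
DEFAULT_SHADING_BLUR_UM = 680.0 / (2.0 * 1.2815515655446004)

#: fraction of the black->white span below which shading counts as dark zone
DARK_ZONE_QUANTILE = 0.20

#: cells cannot be placed closer than this many pixels even when the cell
#: diameter is below it (nuclei spots become unresolvable on the pixel grid)
MIN_SEPARATION_PX = 2.5


@dataclass(frozen=True)
class SceneParams:
    """All knobs of a synthetic scene; equal params mean identical scenes."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 10.0
    pattern: PatternSpec | None = None  # None -> default 450 um / 900 um sheet
    shading_blur_um: float = DEFAULT_SHADING_BLUR_UM
    black_level: float = 0.15
    white_level: float = 0.85
    n_cells: int = 200
    cell_diameter_um: tuple[float, float] = (15.0, 20.0)
    cell_amplitude: float = 0.15
    visibility_coupling: float = 0.8
    n_debris: int = 5
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.shading_blur_um <= 0:
            raise ValueError("shading_blur_um must be positive")
        if not (0.0 <= self.black_level < self.white_level <= 1.0):
            raise ValueError("need 0 <= black_level < white_level <= 1")
        if self.n_cells < 0 or self.n_debris < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.cell_diameter_um
        if not (0 < lo <= hi):
            raise ValueError("cell_diameter_um must be a (lo, hi) range")
        if not (0.0 <= self.visibility_coupling <= 1.0):
            raise ValueError("visibility_coupling must be in [0, 1]")
        if self.cell_amplitude <= 0:
            raise ValueError("cell_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def resolved_pattern(self) -> PatternSpec:
        if self.pattern is not None:
            return self.pattern
        return PatternSpec(
            hole_diameter_um=450.0,
            pitch_um=900.0,
            lattice="square",
            sheet_width_um=self.width_px * self.pixel_size_um,
            sheet_height_um=self.height_px * self.pixel_size_um,
        )


@dataclass
class TruthSet:
    """Ground truth of a synthetic scene (0-based (row, col), origin top-left)."""

    cell_centroids: np.ndarray  # (n, 2) float px
    cell_diameters_um: np.ndarray  # (n,)
    debris_centroids: np.ndarray  # (m, 2) float px
    dark_zone_mask: np.ndarray  # bool map
    gradient_map: np.ndarray  # normalized local shading gradient in [0, 1]

    def __post_init__(self) -> None:
        self.cell_centroids = np.asarray(self.cell_centroids, float).reshape(-1, 2)
        self.debris_centroids = np.asarray(self.debris_centroids, float).reshape(-1, 2)
        self.cell_diameters_um = np.asarray(self.cell_diameters_um, float)
        if len(self.cell_centroids) != len(self.cell_diameters_um):
            raise ValueError("one diameter per cell centroid required")
        h, w = self.dark_zone_mask.shape
        for pts in (self.cell_centroids, self.debris_centroids):
            if len(pts) and (
                pts[:, 0].min() < 0 or pts[:, 0].max() >= h
                or pts[:, 1].min() < 0 or pts[:, 1].max() >= w
            ):
                raise ValueError("centroids must lie inside image bounds")


@dataclass
class SyntheticScene:
    scan: np.ndarray
    phase: np.ndarray
    nuclei: np.ndarray
    truth: TruthSet
    params: SceneParams
    #: additive cell/debris perturbation stamped into the scan, before noise;
    #: exposed so visibility properties are directly testable
    scan_perturbation: np.ndarray = field(default=None, repr=False)


class PlacementError(RuntimeError):
    """Requested object count cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# shading


def render_shading(pattern: PatternSpec, params: SceneParams) -> np.ndarray:
    """Shading field cast by a pattern sheet, in [black_level, white_level].

    Rasterizes the holes at the scene's pixel size, maps open/closed to
    white/black and low-passes with a Gaussian whose sigma is chosen so the
    10-90% transition across a straight boundary spans ~680 um.  Rejects
    patterns whose pitch is below twice the blur: neighbouring bands would
    merge and no flat black or white zones would remain.
    """
    from .ivm import gaussian_blur

    if pattern.pitch_um < 2.0 * params.shading_blur_um:
        raise ValueError(
            f"pattern pitch {pattern.pitch_um} um < 2 x shading blur "
            f"{params.shading_blur_um:.1f} um: transition bands would merge"
        )
    mask = rasterize_pattern(pattern, params.pixel_size_um)
    h, w = params.height_px, params.width_px
    full = np.zeros((h, w), dtype=bool)
    full[: min(h, mask.shape[0]), : min(w, mask.shape[1])] = mask[:h, :w]
    field_ = np.where(full, params.white_level, params.black_level)
    if not full.any() or full.all():
        return field_.astype(float)
    sigma_px = params.shading_blur_um / params.pixel_size_um
    out = gaussian_blur(field_, sigma_px)
    return np.clip(out, params.black_level, params.white_level)


def _normalized_gradient(shading: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(shading)
    g = np.hypot(gy, gx)
    top = g.max()
    return g / top if top > 0 else g


def measure_transition_width(
    profile: np.ndarray, px_um: float, lo: float = 0.1, hi: float = 0.9
) -> float:
    """10-90% width (um) of a monotone transition sampled along a line.

    The span is the profile's own min-max range; crossings are located by
    linear interpolation.
    """
    p = np.asarray(profile, float)
    span = p.max() - p.min()
    if span <= 0:
        raise ValueError("profile is flat")
    t = (p - p.min()) / span
    if p[0] > p[-1]:
        t = t[::-1]

    def crossing(level: float) -> float:
        idx = np.nonzero(t >= level)[0][0]
        if idx == 0:
            return 0.0
        f = (level - t[idx - 1]) / (t[idx] - t[idx - 1])
        return idx - 1 + f

    return (crossing(hi) - crossing(lo)) * px_um


# ---------------------------------------------------------------------------
# object stamps


def _dipole_stamp(shape, center, radius_px, amplitude, angle):
    """Zero-mean radial dipole: a bright and a dark crescent facing each other.

    Mimics how a refractive cell displaces light across a shading gradient
    without claiming optical fidelity.  Returns an additive patch for the
    full image (only a small window is touched).
    """
    h, w = shape
    r0, c0 = center
    R = radius_px
    i0, i1 = max(0, int(r0 - R - 1)), min(h, int(r0 + R + 2))
    j0, j1 = max(0, int(c0 - R - 1)), min(w, int(c0 + R + 2))
    if i0 >= i1 or j0 >= j1:
        return None, (0, 0)
    dy = np.arange(i0, i1)[:, None] - r0
    dx = np.arange(j0, j1)[None, :] - c0
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    u = rho / R
    # radial envelope u*exp(-2u^2), normalized to peak 1 at u = 0.5
    g = u * np.exp(-2.0 * u * u) / (0.5 * math.exp(-0.5))
    g[u > 1.2] = 0.0
    patch = amplitude * np.cos(theta - angle) * g
    return patch, (i0, j0)


def _gaussian_spot(shape, center, sigma_px, amplitude):
    h, w = shape
    r0, c0 = center
    R = 4 * sigma_px + 1
    i0, i1 = max(0, int(r0 - R)), min(h, int(r0 + R + 1))
    j0, j1 = max(0, int(c0 - R)), min(w, int(c0 + R + 1))
    if i0 >= i1 or j0 >= j1:
        return None, (0, 0)
    dy = np.arange(i0, i1)[:, None] - r0
    dx = np.arange(j0, j1)[None, :] - c0
    patch = amplitude * np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_px**2))
    return patch, (i0, j0)


def _add_patch(img, patch, origin):
    if patch is None:
        return
    i0, j0 = origin
    img[i0 : i0 + patch.shape[0], j0 : j0 + patch.shape[1]] += patch


def _place_points(rng, n, h, w, min_sep_px, margin, what="cells"):
    """Uniform rejection sampling with a 100x retry budget per object."""
    pts = np.empty((0, 2))
    if n == 0:
        return pts
    placed = []
    attempts_left = 100 * n
    while len(placed) < n and attempts_left > 0:
        attempts_left -= 1
        p = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep_px**2
               for q in placed):
            placed.append(p)
    if len(placed) < n:
        raise PlacementError(
            f"could only place {len(placed)} of {n} {what} without overlap "
            f"(min separation {min_sep_px:.1f} px); reduce the count or density"
        )
    return np.asarray(placed)


def _illumination_factor(shading, params):
    """Visibility attenuation in deep shadow.

    Cells sitting in the darkest parts of the shading pattern receive little
    light and their perturbation shrinks accordingly; this is what gives the
    detector natural blind spots.  Ramps linearly from 0.15 at the black level
    to 1.0 at 30% of the span.
    """
    span = params.white_level - params.black_level
    t = np.clip((shading - params.black_level) / (0.3 * span), 0.0, 1.0)
    return 0.15 + 0.85 * t


# ---------------------------------------------------------------------------
# scene rendering


def render_scene(params: SceneParams) -> SyntheticScene:
    """Render a scan/phase/nuclei triplet with exact ground truth.

    Cell perturbation amplitude in the scan is
    ``cell_amplitude * (vc * g + (1 - vc)) * illum`` where ``g`` is the
    normalized local shading gradient, ``vc`` the visibility coupling and
    ``illum`` the deep-shadow attenuation; with ``vc = 1`` cells stamped in
    flat shading zones vanish entirely.  Debris uses a fixed, unmodulated
    amplitude and is stamped in scan and phase but never in nuclei, so it is
    countable downstream as an image-origin false positive.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    shape = (h, w)
    pattern = params.resolved_pattern()
    shading = render_shading(pattern, params)
    grad = _normalized_gradient(shading)
    span = params.white_level - params.black_level
    dark_zone = shading < params.black_level + DARK_ZONE_QUANTILE * span
    illum = _illumination_factor(shading, params)

    d_lo, d_hi = params.cell_diameter_um
    mean_d_px = 0.5 * (d_lo + d_hi) / params.pixel_size_um
    min_sep = max(mean_d_px, MIN_SEPARATION_PX)
    margin = 3.0
    cells = _place_points(rng, params.n_cells, h, w, min_sep, margin, "cells")
    diameters = rng.uniform(d_lo, d_hi, size=len(cells))
    debris = _place_points(rng, params.n_debris, h, w, min_sep, margin, "debris")
    debris_diam = rng.uniform(10.0, 30.0, size=len(debris))

    vc = params.visibility_coupling
    perturb = np.zeros(shape)
    phase = np.full(shape, 0.25)
    nuclei = np.zeros(shape)

    for (r0, c0), d_um in zip(cells, diameters):
        d_px = d_um / params.pixel_size_um
        radius = d_px / 2.0 + 1.0
        pr, pc = int(round(r0)), int(round(c0))
        g_loc = grad[pr, pc]
        amp = params.cell_amplitude * (vc * g_loc + (1.0 - vc)) * illum[pr, pc]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        patch, org = _dipole_stamp(shape, (r0, c0), radius, amp, angle)
        _add_patch(perturb, patch, org)
        spot, org = _gaussian_spot(shape, (r0, c0), 0.9, 0.55)
        _add_patch(phase, spot, org)
        nuc, org = _gaussian_spot(shape, (r0, c0), 0.5, 1.0)
        _add_patch(nuclei, nuc, org)

    for (r0, c0), d_um in zip(debris, debris_diam):
        radius = d_um / params.pixel_size_um / 2.0 + 1.0
        angle = rng.uniform(0.0, 2.0 * math.pi)
        patch, org = _dipole_stamp(shape, (r0, c0), radius, params.cell_amplitude,
                                   angle)
        _add_patch(perturb, patch, org)
        spot, org = _gaussian_spot(shape, (r0, c0), 0.9, 0.45)
        _add_patch(phase, spot, org)

    scan = shading + perturb
    if params.noise_sd > 0:
        scan = scan + rng.normal(0.0, params.noise_sd, size=shape)
    scan = np.clip(scan, 0.0, 1.0)
    nuclei = np.clip(nuclei, 0.0, 1.0)
    phase = np.clip(phase, 0.0, 1.0)

    truth = TruthSet(cells, diameters, debris, dark_zone, grad)
    return SyntheticScene(scan, phase, nuclei, truth, params, perturb)


def n_cells_for_density(density_cells_per_cm2: float, params: SceneParams) -> int:
    """Convert a target seeding density into a cell count for the scene area."""
    if density_cells_per_cm2 < 0:
        raise ValueError("density must be nonnegative")
    area_cm2 = (
        params.width_px * params.height_px * (params.pixel_size_um * 1e-4) ** 2
    )
    return int(round(density_cells_per_cm2 * area_cm2))


def count_nuclei_blobs(nuclei: np.ndarray, threshold: float = 0.3) -> int:
    """Count bright nuclei spots by thresholding and connected components.

    The default threshold sits below the worst-case peak pixel value of a
    unit-amplitude sigma=0.5 px spot centered between pixels (exp(-1) ~ 0.37)
    and above the midpoint value of two spots at the minimum placement
    separation, so for non-overlapping placements the blob count equals the
    cell count.
    """
    from scipy import ndimage as ndi

    _, n = ndi.label(nuclei > threshold)
    return n


# ---------------------------------------------------------------------------
# growth series


@dataclass(frozen=True)
class GrowthCurve:
    """Exponential growth with an optional logistic carrying capacity."""

    n0: int
    doubling_time_min: float
    capacity: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.doubling_time_min <= 0:
            raise ValueError("doubling time must be positive")
        if self.capacity is not None and self.capacity < self.n0:
            raise ValueError("capacity must be >= n0")

    def count_at(self, t_min: float) -> int:
        n = self.n0 * 2.0 ** (t_min / self.doubling_time_min)
        if self.capacity is not None:
            k, n0 = float(self.capacity), float(self.n0)
            growth = 2.0 ** (t_min / self.doubling_time_min)
            n = k * n0 * growth / (k + n0 * (growth - 1.0))
        return int(round(n))


def growth_series(
    params: SceneParams,
    n_frames: int,
    interval_min: float,
    growth: GrowthCurve,
) -> list[SyntheticScene]:
    """Coherent time-lapse: frame t holds round(curve(t)) cells.

    Cell positions persist across frames (earlier frames' cells are a prefix
    of later frames'), so a fixed field of view sees a consistent history.
    Frame-local randomness (stamp angles, noise) is drawn from per-frame
    seeds spawned deterministically from the scene seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    if n_frames == 1:
        return [render_scene(replace(params, n_cells=growth.count_at(0.0)))]

    counts = [growth.count_at(t * interval_min) for t in range(n_frames)]
    n_max = max(counts)
    # master placement: positions/diameters for the maximum population,
    # sampled once so prefixes are shared by all frames
    master_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC0]))
    h, w = params.height_px, params.width_px
    d_lo, d_hi = params.cell_diameter_um
    mean_d_px = 0.5 * (d_lo + d_hi) / params.pixel_size_um
    min_sep = max(mean_d_px, MIN_SEPARATION_PX)
    positions = _place_points(master_rng, n_max, h, w, min_sep, 3.0, "cells")
    diameters = master_rng.uniform(d_lo, d_hi, size=n_max)

    seeds = np.random.SeedSequence([params.seed, 0xF1]).generate_state(n_frames)
    frames = []
    for t, n_t in enumerate(counts):
        frame_params = replace(params, n_cells=n_t, seed=int(seeds[t] % 2**31))
        scene = _render_with_positions(
            frame_params, positions[:n_t], diameters[:n_t]
        )
        frames.append(scene)
    return frames


def _render_with_positions(params, positions, diameters):
    """Render a scene around externally fixed cell positions."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    shape = (h, w)
    shading = render_shading(params.resolved_pattern(), params)
    grad = _normalized_gradient(shading)
    span = params.white_level - params.black_level
    dark_zone = shading < params.black_level + DARK_ZONE_QUANTILE * span
    illum = _illumination_factor(shading, params)
    vc = params.visibility_coupling

    perturb = np.zeros(shape)
    phase = np.full(shape, 0.25)
    nuclei = np.zeros(shape)
    for (r0, c0), d_um in zip(positions, diameters):
        d_px = d_um / params.pixel_size_um
        radius = d_px / 2.0 + 1.0
        pr, pc = int(round(r0)), int(round(c0))
        g_loc = grad[pr, pc]
        amp = params.cell_amplitude * (vc * g_loc + (1.0 - vc)) * illum[pr, pc]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        patch, org = _dipole_stamp(shape, (r0, c0), radius, amp, angle)
        _add_patch(perturb, patch, org)
        spot, org = _gaussian_spot(shape, (r0, c0), 0.9, 0.55)
        _add_patch(phase, spot, org)
        nuc, org = _gaussian_spot(shape, (r0, c0), 0.5, 1.0)
        _add_patch(nuclei, nuc, org)

    debris = _place_points(rng, params.n_debris, h, w,
                           max(MIN_SEPARATION_PX, 2.5), 3.0, "debris")
    for (r0, c0), d_um in zip(debris, rng.uniform(10.0, 30.0, len(debris))):
        radius = d_um / params.pixel_size_um / 2.0 + 1.0
        angle = rng.uniform(0.0, 2.0 * math.pi)
        patch, org = _dipole_stamp(shape, (r0, c0), radius,
                                   params.cell_amplitude, angle)
        _add_patch(perturb, patch, org)
        spot, org = _gaussian_spot(shape, (r0, c0), 0.9, 0.45)
        _add_patch(phase, spot, org)

    scan = shading + perturb
    if params.noise_sd > 0:
        scan = scan + rng.normal(0.0, params.noise_sd, size=shape)
    truth = TruthSet(np.asarray(positions), np.asarray(diameters),
                     debris, dark_zone, grad)
    return SyntheticScene(
        np.clip(scan, 0.0, 1.0), np.clip(phase, 0.0, 1.0),
        np.clip(nuclei, 0.0, 1.0), truth, params, perturb,
    )
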