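"""Simplified 2-D Monte-Carlo ray tracer for the pattern-sheet mechanism.

The scanner's diffuse LED is modelled as a row of point emitters with uniform
angular emission inside a half-angle.  Rays cross an opaque aperture sheet
(the pattern-sheet cross-section), interact with circular model cells of
refractive index 1.360 sitting in medium of index 1.335 — at each cell-circle
intersection a ray is either scattered into a uniform random direction with
probability ``diffusion_ratio`` (0.3) or refracted by Snell's law — and are
finally binned on a sensor line (ideal straight-line propagation; no lens).

The model demonstrates the qualitative mechanism only: with restricted,
inhomogeneous illumination the refraction and scattering by cells produce
sensor contrast, while under wide diffuse illumination (no sheet, or the
sheet replaced by an 80% diffuser) the redistributed rays average out and the
cells leave almost no signature.

One lateral axis (x, um) plus the optical axis (z, um); source plane at z=0.
All per-ray randomness is pre-drawn from the seed, so runs are deterministic
and two configs differing only in their apertures are exactly coupled
(adding apertures can only add binned rays, never remove them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CELL_RI = 1.360
MEDIUM_RI = 1.335
DIFFUSION_RATIO = 0.3
_MAX_EVENTS = 6
_EPS_UM = 1e-6


@dataclass(frozen=True)
class RaySimConfig:
    """Geometry and sampling settings of one trace."""

    source_extent_um: float = 12000.0
    n_source_points: int = 601
    source_half_angle_deg: float = 30.0
    sheet_z_um: float = 4900.0
    #: open intervals (x0, x1) of the sheet cross-section; None = no sheet
    apertures_um: tuple | None = None
    #: probability that the sheet plane re-randomizes a ray's direction
    #: (diffuser condition); None disables the diffuser
    diffuser_strength: float | None = None
    cells_z_um: float = 5000.0
    #: circular model cells as (center_x_um, radius_um)
    cells: tuple = ((0.0, 100.0),)
    cell_ri: float = CELL_RI
    medium_ri: float = MEDIUM_RI
    diffusion_ratio: float = DIFFUSION_RATIO
    sensor_z_um: float = 5500.0
    sensor_extent_um: float = 6000.0
    n_bins: int = 120
    n_rays: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sheet_z_um < self.cells_z_um < self.sensor_z_um):
            raise ValueError("need source(0) < sheet < cells < sensor on z")
        if self.n_rays <= 0:
            raise ValueError("n_rays must be positive")
        if not (0.0 <= self.diffusion_ratio <= 1.0):
            raise ValueError("diffusion_ratio must be in [0, 1]")
        if self.diffuser_strength is not None and not (
            0.0 <= self.diffuser_strength <= 1.0
        ):
            raise ValueError("diffuser_strength must be in [0, 1]")
        if self.cell_ri <= 0 or self.medium_ri <= 0:
            raise ValueError("refractive indices must be positive")


@dataclass
class SensorProfile:
    bin_edges_um: np.ndarray
    illuminance: np.ndarray  # ray counts per bin, arbitrary units
    n_absorbed: int
    n_scattered_out: int
    config: RaySimConfig = field(repr=False, default=None)

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    @property
    def n_binned(self) -> int:
        return int(self.illuminance.sum())


def snell_refract(direction, normal, n1: float, n2: float):
    """Refract a unit 2-vector at an interface; None signals TIR.

    ``normal`` must be a unit vector pointing against the incident ray
    (``direction . normal < 0``).  Implements sin(theta2) =
    (n1/n2) sin(theta1) in the incidence plane.
    """
    d = np.asarray(direction, float)
    n = np.asarray(normal, float)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("indices must be positive")
    if np.allclose(d, 0) or np.allclose(n, 0):
        raise ValueError("zero vectors are not valid directions")
    d = d / np.linalg.norm(d)
    n = n / np.linalg.norm(n)
    mu = n1 / n2
    cos_i = -float(np.dot(d, n))
    sin_t2 = mu * mu * (1.0 - cos_i * cos_i)
    if sin_t2 > 1.0:
        return None
    cos_t = math.sqrt(1.0 - sin_t2)
    return mu * d + (mu * cos_i - cos_t) * n


def _refract_vec(dx, dz, nx, nz, mu):
    """Vectorized Snell; returns new (dx, dz) and a TIR mask."""
    cos_i = -(dx * nx + dz * nz)
    sin_t2 = mu * mu * (1.0 - cos_i * cos_i)
    tir = sin_t2 > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, None))
    k = mu * cos_i - cos_t
    rx = mu * dx + k * nx
    rz = mu * dz + k * nz
    # TIR: mirror reflection about the interface
    dot = dx * nx + dz * nz
    rx = np.where(tir, dx - 2.0 * dot * nx, rx)
    rz = np.where(tir, dz - 2.0 * dot * nz, rz)
    return rx, rz, tir


def trace(config: RaySimConfig) -> SensorProfile:
    """Trace ``n_rays`` through sheet and cells onto the sensor line.

    Ray conservation holds exactly:
    ``n_absorbed + n_scattered_out + n_binned == n_rays``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_rays

    # pre-draw all randomness so paths are coupled across aperture configs
    if config.n_source_points > 1:
        src_x = np.linspace(
            -config.source_extent_um / 2, config.source_extent_um / 2,
            config.n_source_points,
        )
        x = src_x[rng.integers(0, config.n_source_points, n)]
    else:
        x = np.zeros(n)
    ha = math.radians(config.source_half_angle_deg)
    theta = rng.uniform(-ha, ha, n)
    diffuser_u = rng.random(n)
    diffuser_theta = rng.uniform(-ha, ha, n)
    scatter_u = rng.random((_MAX_EVENTS, n))
    scatter_theta = rng.uniform(0.0, 2.0 * math.pi, (_MAX_EVENTS, n))

    dx, dz = np.sin(theta), np.cos(theta)
    z = np.zeros(n)
    absorbed = np.zeros(n, dtype=bool)

    # --- sheet plane ---------------------------------------------------
    t = (config.sheet_z_um - z) / dz
    x = x + dx * t
    z = np.full(n, config.sheet_z_um)
    if config.apertures_um is not None:
        inside = np.zeros(n, dtype=bool)
        for x0, x1 in config.apertures_um:
            inside |= (x >= x0) & (x <= x1)
        absorbed |= ~inside
    elif config.diffuser_strength is not None:
        scat = diffuser_u < config.diffuser_strength
        dx = np.where(scat, np.sin(diffuser_theta), dx)
        dz = np.where(scat, np.cos(diffuser_theta), dz)

    # --- cell interactions ---------------------------------------------
    cells = np.asarray(config.cells, float).reshape(-1, 2)
    mu_in = config.medium_ri / config.cell_ri
    mu_out = config.cell_ri / config.medium_ri
    active = ~absorbed
    for ev in range(_MAX_EVENTS if len(cells) else 0):
        # nearest forward intersection with any cell circle
        t_hit = np.full(n, np.inf)
        hit_cell = np.full(n, -1)
        for i, (cx, r) in enumerate(cells):
            mx = x - cx
            mz = z - config.cells_z_um
            b = mx * dx + mz * dz
            c = mx * mx + mz * mz - r * r
            disc = b * b - c
            ok = active & (disc > 0)
            sq = np.sqrt(np.where(disc > 0, disc, 0.0))
            t1 = -b - sq
            t2 = -b + sq
            t_c = np.where(t1 > _EPS_UM, t1, np.where(t2 > _EPS_UM, t2, np.inf))
            better = ok & (t_c < t_hit)
            t_hit = np.where(better, t_c, t_hit)
            hit_cell = np.where(better, i, hit_cell)

        hitting = active & np.isfinite(t_hit)
        if not hitting.any():
            break
        x = np.where(hitting, x + dx * t_hit, x)
        z = np.where(hitting, z + dz * t_hit, z)

        # outward normal at the hit point
        cx_hit = np.where(hit_cell >= 0, cells[np.clip(hit_cell, 0, None), 0], 0.0)
        r_hit = np.where(hit_cell >= 0, cells[np.clip(hit_cell, 0, None), 1], 1.0)
        nx = (x - cx_hit) / r_hit
        nz = (z - config.cells_z_um) / r_hit

        scat = hitting & (scatter_u[ev] < config.diffusion_ratio)
        dx = np.where(scat, np.sin(scatter_theta[ev]), dx)
        dz = np.where(scat, np.cos(scatter_theta[ev]), dz)

        refracting = hitting & ~scat
        entering = (dx * nx + dz * nz) < 0
        for going_in in (True, False):
            m = refracting & (entering == going_in)
            if not m.any():
                continue
            sign = 1.0 if going_in else -1.0
            rdx, rdz, _ = _refract_vec(
                dx, dz, sign * nx, sign * nz, mu_in if going_in else mu_out
            )
            dx = np.where(m, rdx, dx)
            dz = np.where(m, rdz, dz)
    # rays still flying after the event budget with a pending hit are dropped
    if len(cells):
        t_final = np.full(n, np.inf)
        for cx, r in cells:
            mx, mz = x - cx, z - config.cells_z_um
            b = mx * dx + mz * dz
            disc = b * b - (mx * mx + mz * mz - r * r)
            sq = np.sqrt(np.where(disc > 0, disc, 0.0))
            t1, t2 = -b - sq, -b + sq
            t_c = np.where(t1 > _EPS_UM, t1, np.where(t2 > _EPS_UM, t2, np.inf))
            t_final = np.where(disc > 0, np.minimum(t_final, t_c), t_final)
        absorbed |= (~absorbed) & np.isfinite(t_final)

    # --- sensor ---------------------------------------------------------
    alive = ~absorbed
    forward = alive & (dz > 1e-12) & (z < config.sensor_z_um)
    out = alive & ~forward
    t = np.where(forward, (config.sensor_z_um - z) / np.where(dz > 0, dz, 1.0), 0.0)
    xf = x + dx * t
    half = config.sensor_extent_um / 2.0
    on_sensor = forward & (np.abs(xf) <= half)
    out |= forward & ~on_sensor

    edges = np.linspace(-half, half, config.n_bins + 1)
    counts, _ = np.histogram(xf[on_sensor], bins=edges)
    return SensorProfile(
        bin_edges_um=edges,
        illuminance=counts.astype(float),
        n_absorbed=int(absorbed.sum()),
        n_scattered_out=int(out.sum()),
        config=config,
    )


def cell_contrast(profile: SensorProfile, cell_positions=None) -> float:
    """Sign-free relative contrast of cell shadows against flanking bins.

    For each cell, bins whose centers lie within one radius of the cell
    center (projected straight down onto the sensor) form the shadow set;
    bins between one and three radii away, excluding other cells' shadows,
    form the flanking background.  Contrast is |mean_shadow - mean_flank| /
    mean_flank, averaged over cells.
    """
    if cell_positions is None:
        cell_positions = profile.config.cells
    cells = np.asarray(cell_positions, float).reshape(-1, 2)
    centers = profile.bin_centers_um
    in_any_shadow = np.zeros(len(centers), dtype=bool)
    for cx, r in cells:
        in_any_shadow |= np.abs(centers - cx) <= r
    contrasts = []
    for cx, r in cells:
        shadow = np.abs(centers - cx) <= r
        flank = (np.abs(centers - cx) > r) & (np.abs(centers - cx) <= 3 * r)
        flank &= ~in_any_shadow
        if not flank.any() or not shadow.any():
            raise ValueError("empty shadow or background bin set for a cell")
        bg = profile.illuminance[flank].mean()
        if bg <= 0:
            raise ValueError("background illuminance is zero")
        contrasts.append(abs(profile.illuminance[shadow].mean() - bg) / bg)
    return float(np.mean(contrasts))


def pattern_apertures(
    hole_diameter_um: float = 450.0,
    pitch_um: float = 900.0,
    extent_um: float = 8000.0,
) -> tuple:
    """1-D cross-section of a hole pattern: open intervals through hole centers."""
    k_max = int(extent_um / 2 / pitch_um) + 1
    half = hole_diameter_um / 2.0
    return tuple(
        (k * pitch_um - half, k * pitch_um + half)
        for k in range(-k_max, k_max + 1)
    )


def demo_config(condition: str = "sheet", n_rays: int = 1_000_000,
                seed: int = 0) -> RaySimConfig:
    """Desk-scale demo geometry for the three illumination conditions.

    ``condition`` is ``"sheet"`` (450-um-hole pattern cross-section),
    ``"nosheet"`` (unrestricted diffuse light) or ``"diffuser"`` (sheet
    replaced by an 80% direction-randomizing diffuser).  Five model cells of
    100 um radius sit at different phases of the shadow pattern.  The wide
    source makes the no-sheet illumination fully diffuse at the cell plane,
    and the sheet sits just below the vessel so its shadow pattern stays
    crisp (penumbra ~ source_extent x (cells_z - sheet_z) / sheet_z).
    """
    cells = tuple((float(cx), 100.0) for cx in (-1600, -800, 0, 800, 1600))
    common = dict(cells=cells, n_rays=n_rays, seed=seed)
    if condition == "sheet":
        return RaySimConfig(apertures_um=pattern_apertures(), **common)
    if condition == "nosheet":
        return RaySimConfig(**common)
    if condition == "diffuser":
        return RaySimConfig(diffuser_strength=0.8, **common)
    raise ValueError(f"unknown condition {condition!r}")
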