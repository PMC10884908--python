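"""Synthetic scene generator: determinism, shading, placement, growth."""

import dataclasses

import numpy as np
import pytest

from sheetscan.pattern import PatternSpec
from sheetscan.synthetic import (
    GrowthCurve,
    PlacementError,
    SceneParams,
    count_nuclei_blobs,
    growth_series,
    measure_transition_width,
    n_cells_for_density,
    render_scene,
    render_shading,
)

FLAT_PATTERN = PatternSpec(  # only hole lies >4 sigma outside the image window
    hole_diameter_um=500.0, pitch_um=5000.0,
    sheet_width_um=5100.0, sheet_height_um=5100.0,
)


def test_scene_params_validation():
    with pytest.raises(ValueError):
        SceneParams(black_level=0.9, white_level=0.1)
    with pytest.raises(ValueError):
        SceneParams(visibility_coupling=1.5)
    with pytest.raises(ValueError):
        SceneParams(width_px=0)


def test_seed_determinism_bit_identical():
    p = SceneParams(width_px=256, height_px=256, n_cells=40, seed=7)
    a, b = render_scene(p), render_scene(p)
    np.testing.assert_array_equal(a.scan, b.scan)
    np.testing.assert_array_equal(a.phase, b.phase)
    np.testing.assert_array_equal(a.nuclei, b.nuclei)
    np.testing.assert_array_equal(a.truth.cell_centroids, b.truth.cell_centroids)


def test_empty_scene_equals_shading():
    p = SceneParams(width_px=256, height_px=256, n_cells=0, n_debris=0,
                    noise_sd=0.0, seed=0)
    scene = render_scene(p)
    shading = render_shading(p.resolved_pattern(), p)
    np.testing.assert_array_equal(scene.scan, shading)


def test_shading_constant_when_no_boundary_in_window():
    p = SceneParams(width_px=128, height_px=128, pattern=FLAT_PATTERN, n_cells=0)
    sh = render_shading(FLAT_PATTERN, p)
    assert np.ptp(sh) == 0.0 and sh[0, 0] == p.black_level


def test_shading_levels_and_band_merging_rejected():
    p = SceneParams(width_px=256, height_px=256, n_cells=0)
    sh = render_shading(p.resolved_pattern(), p)
    assert sh.min() >= p.black_level and sh.max() <= p.white_level
    tight = PatternSpec(hole_diameter_um=200.0, pitch_um=400.0,
                        sheet_width_um=3000.0, sheet_height_um=3000.0)
    with pytest.raises(ValueError):
        render_shading(tight, p)


def test_transition_width_near_680_um():
    """10-90% width across a locally straight boundary ~ 680 um +- 20%."""
    big = PatternSpec(hole_diameter_um=6000.0, pitch_um=9000.0,
                      sheet_width_um=10240.0, sheet_height_um=10240.0)
    p = SceneParams(width_px=1024, height_px=1024, n_cells=0)
    sh = render_shading(big, p)
    width = measure_transition_width(sh[512, :512], p.pixel_size_um)
    assert 680.0 * 0.8 < width < 680.0 * 1.2


def test_nuclei_blob_count_equals_cell_count():
    for seed in range(3):
        s = render_scene(SceneParams(width_px=512, height_px=512,
                                     n_cells=120, seed=seed))
        assert count_nuclei_blobs(s.nuclei) == 120


def test_debris_absent_from_nuclei_channel():
    s = render_scene(SceneParams(width_px=256, height_px=256, n_cells=0,
                                 n_debris=8, noise_sd=0.0, seed=2))
    assert count_nuclei_blobs(s.nuclei) == 0
    assert np.abs(s.scan_perturbation).max() > 0  # debris do mark the scan


def test_visibility_coupling_suppresses_flat_zone_cells():
    flat = render_scene(
        SceneParams(width_px=128, height_px=128, pattern=FLAT_PATTERN,
                    visibility_coupling=1.0, n_cells=10, n_debris=0,
                    noise_sd=0.0, seed=4)
    )
    assert np.abs(flat.scan_perturbation).max() == 0.0
    banded = render_scene(
        SceneParams(width_px=512, height_px=512, visibility_coupling=1.0,
                    n_cells=40, n_debris=0, noise_sd=0.0, seed=4)
    )
    assert np.abs(banded.scan_perturbation).max() > 0.0


def test_min_separation_respected():
    s = render_scene(SceneParams(width_px=512, height_px=512, n_cells=150, seed=5))
    pts = s.truth.cell_centroids
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    d[np.diag_indices(len(pts))] = np.inf
    assert d.min() >= 2.5 - 1e-9  # max(mean cell diameter, 2.5 px) floor


def test_unplaceable_count_raises_with_achievable_max():
    with pytest.raises(PlacementError, match=r"could only place"):
        render_scene(SceneParams(width_px=32, height_px=32, n_cells=500,
                                 pattern=FLAT_PATTERN, seed=0))


def test_uniform_placement_passes_chi_square():
    """5x5 field counts consistent with multinomial dispersion, pooled seeds."""
    from scipy import stats

    chi_tot, dof_tot = 0.0, 0
    for seed in range(4):
        s = render_scene(SceneParams(width_px=1000, height_px=1000,
                                     n_cells=200, n_debris=0, seed=seed))
        pts = s.truth.cell_centroids
        edges = np.linspace(3.0, 996.0, 6)
        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
        chi_tot += ((h - 8.0) ** 2 / 8.0).sum()
        dof_tot += 24
    assert 1.0 - stats.chi2.cdf(chi_tot, dof_tot) > 0.01


def test_density_to_count_conversion():
    p = SceneParams(width_px=1000, height_px=1000)  # exactly 1 cm^2 at 10 um/px
    assert n_cells_for_density(250.0, p) == 250


# ---------------------------------------------------------------------------
# growth series


def test_growth_curve_doubling_and_validation():
    g = GrowthCurve(n0=10, doubling_time_min=30.0)
    assert [g.count_at(t) for t in (0.0, 30.0, 60.0)] == [10, 20, 40]
    with pytest.raises(ValueError):
        GrowthCurve(n0=10, doubling_time_min=-5.0)


def test_growth_single_frame_identical_to_render_scene():
    p = SceneParams(width_px=128, height_px=128, pattern=FLAT_PATTERN,
                    n_cells=99, seed=6)
    frames = growth_series(p, 1, 30.0, GrowthCurve(n0=12, doubling_time_min=60.0))
    direct = render_scene(dataclasses.replace(p, n_cells=12))
    np.testing.assert_array_equal(frames[0].scan, direct.scan)


def test_growth_counts_and_position_persistence():
    p = SceneParams(width_px=256, height_px=256, n_cells=0, n_debris=0,
                    noise_sd=0.0, seed=8)
    frames = growth_series(p, 3, 30.0, GrowthCurve(n0=10, doubling_time_min=30.0))
    counts = [len(f.truth.cell_centroids) for f in frames]
    assert counts == [10, 20, 40]
    # earlier frames' cells are a prefix of later frames'
    np.testing.assert_array_equal(
        frames[0].truth.cell_centroids,
        frames[2].truth.cell_centroids[:10],
    )


def test_growth_timelapse_spans_132_hours():
    """265 frames at 30-min intervals cover 0 to 132 h of culture time."""
    n_frames, interval_min = 265, 30.0
    assert (n_frames - 1) * interval_min / 60.0 == 132.0
    g = GrowthCurve(n0=5, doubling_time_min=24 * 60.0, capacity=40)
    frames = growth_series(
        SceneParams(width_px=64, height_px=64, pattern=FLAT_PATTERN,
                    n_cells=0, n_debris=0, noise_sd=0.0, seed=9),
        n_frames, interval_min, g,
    )
    assert len(frames) == n_frames
    assert len(frames[-1].truth.cell_centroids) == g.count_at(
        (n_frames - 1) * interval_min
    )
    assert len(frames[-1].truth.cell_centroids) <= 40  # logistic cap
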