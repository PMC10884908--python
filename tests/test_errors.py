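"""Matching, error taxonomy, and correlation statistics."""

import numpy as np
import pytest

from sheetscan.detect import detect_scan
from sheetscan.errors import (
    ErrorReport,
    accuracy_by_density,
    classify_errors,
    match_detections,
    r_squared,
)
from sheetscan.pattern import PatternSpec
from sheetscan.synthetic import SceneParams, TruthSet, render_scene


def make_truth(cells, diameters, debris=(), dark=None, shape=(100, 100)):
    dark_mask = np.zeros(shape, dtype=bool) if dark is None else dark
    return TruthSet(
        np.asarray(cells, float).reshape(-1, 2),
        np.asarray(diameters, float),
        np.asarray(debris, float).reshape(-1, 2),
        dark_mask,
        np.zeros(shape),
    )


# ---------------------------------------------------------------------------
# matching


def test_identical_centroids_match_perfectly(rng):
    pts = rng.uniform(0, 90, size=(20, 2))
    m = match_detections(pts, pts, 5.0)
    assert len(m.pairs) == 20 and not m.unmatched_det and not m.unmatched_truth
    assert all(t == d for t, d in m.pairs)


def test_equidistant_tie_goes_to_lower_truth_index():
    truth = [(10.0, 10.0), (10.0, 14.0)]
    det = [(10.0, 12.0)]  # exactly 2 px from both truths
    m = match_detections(det, truth, 5.0)
    assert m.pairs == [(0, 0)]
    assert m.unmatched_truth == [1]


def test_pairs_beyond_radius_never_match():
    m = match_detections([(0.0, 0.0)], [(50.0, 50.0)], 5.0)
    assert not m.pairs


def test_greedy_agrees_with_optimal_assignment_when_costs_agree(rng):
    """Exhaustive optimal-assignment oracle on small random configurations."""
    from scipy.optimize import linear_sum_assignment

    agreements = 0
    for _ in range(30):
        n = int(rng.integers(2, 9))
        truth = rng.uniform(0, 40, size=(n, 2))
        det = truth + rng.normal(0, 2.0, size=(n, 2))
        m = match_detections(det, truth, max_dist_px=100.0)
        cost = np.linalg.norm(truth[:, None] - det[None, :], axis=2)
        ti, di = linear_sum_assignment(cost)
        greedy_cost = sum(cost[t, d] for t, d in m.pairs)
        if np.isclose(greedy_cost, cost[ti, di].sum()):
            assert set(m.pairs) == set(zip(ti.tolist(), di.tolist()))
            agreements += 1
        assert len(m.pairs) == n  # same cardinality regardless
    assert agreements >= 20  # greedy is usually optimal on near-identity maps


# ---------------------------------------------------------------------------
# classification


def test_perfect_detection_has_zero_errors():
    cells = [(10.0, 10.0), (30.0, 30.0), (50.0, 50.0)]
    truth = make_truth(cells, [17.0, 18.0, 16.0])
    m = match_detections(cells, truth, 5.0)
    rep = classify_errors(m, np.asarray(cells), truth)
    assert rep.matched == 3
    assert (rep.over_image_origin, rep.over_large_cell,
            rep.under_blind_spot, rep.under_resolution) == (0, 0, 0, 0)


def test_single_debris_detection_is_one_percent():
    cells = [(float(i), 50.0) for i in range(100)]
    truth = make_truth(cells, [17.0] * 100, debris=[(80.0, 90.0)],
                       shape=(120, 120))
    det = np.vstack([np.asarray(cells), [[80.0, 90.0]]])
    m = match_detections(det, truth, 2.0)
    rep = classify_errors(m, det, truth)
    assert rep.over_image_origin == 1
    assert rep.percentages()["over_image_origin_pct"] == pytest.approx(1.0)


def test_four_error_categories_classified_as_designed():
    """Hand-built scene: exactly one error of each of the four types."""
    dark = np.zeros((100, 100), dtype=bool)
    dark[65:75, 65:75] = True
    truth = make_truth(
        cells=[(10, 10), (30, 30), (70, 70), (90, 10), (90, 13)],
        diameters=[17.0, 30.0, 16.0, 17.0, 18.0],
        debris=[(50.0, 50.0)],
        dark=dark,
    )
    det = np.array([
        (10.0, 10.0),   # matches cell 0
        (28.0, 30.0),   # matches large cell 1
        (32.0, 30.0),   # second detection of large cell 1 -> large-cell error
        (50.0, 50.0),   # debris -> image-origin error
        (90.0, 11.0),   # matches cell 3; cell 4 missed -> resolution error
    ])                   # cell 2 in dark zone undetected -> blind spot
    m = match_detections(det, truth, 5.0)
    rep = classify_errors(m, det, truth)
    assert (rep.over_image_origin, rep.over_large_cell,
            rep.under_blind_spot, rep.under_resolution) == (1, 1, 1, 1)
    assert rep.unclassified_over == 0 and rep.unclassified_under == 0
    pct = rep.percentages()
    assert pct["under_blind_spot_pct"] == pytest.approx(20.0)


def test_missing_aux_layers_reported():
    class Bare:
        cell_centroids = np.zeros((2, 2))

    m = match_detections(np.zeros((1, 2)), Bare.cell_centroids, 5.0)
    with pytest.raises(ValueError, match="missing aux layers"):
        classify_errors(m, np.zeros((1, 2)), Bare)


def test_report_identities_enforced():
    with pytest.raises(ValueError):
        ErrorReport(n_truth=5, n_detected=5, matched=4, over_image_origin=0,
                    over_large_cell=0, under_blind_spot=1, under_resolution=0,
                    unclassified_over=0, unclassified_under=0)


def test_accounting_identities_on_generated_scenes():
    for seed in (0, 1):
        scene = render_scene(SceneParams(width_px=512, height_px=512,
                                         n_cells=150, seed=seed))
        det = detect_scan(scene.scan)
        m = match_detections(det, scene.truth, 5.0)
        rep = classify_errors(m, det, scene.truth)  # __post_init__ checks
        assert rep.n_detected == len(det)
        assert rep.n_truth == 150


def test_blind_spot_rate_rises_with_dark_area():
    """Sparser holes leave more deep shadow, so more cells go undetected there."""
    means = []
    for pitch in (900.0, 1800.0):
        pat = PatternSpec(hole_diameter_um=450.0, pitch_um=pitch,
                          sheet_width_um=10240.0, sheet_height_um=10240.0)
        rates, dark_fracs = [], []
        for seed in range(3):
            scene = render_scene(SceneParams(pattern=pat, n_cells=300,
                                             n_debris=0, seed=seed))
            det = detect_scan(scene.scan)
            m = match_detections(det, scene.truth, 5.0)
            rep = classify_errors(m, det, scene.truth)
            rates.append(100.0 * rep.under_blind_spot / rep.n_truth)
            dark_fracs.append(scene.truth.dark_zone_mask.mean())
        means.append((np.mean(dark_fracs), np.mean(rates)))
    (dark_a, blind_a), (dark_b, blind_b) = means
    assert dark_b > dark_a
    assert blind_b > blind_a


# ---------------------------------------------------------------------------
# scalar statistics


def test_accuracy_by_density_closed_forms():
    assert accuracy_by_density(100.0, 100.0) == 0.0
    assert accuracy_by_density(110.0, 100.0) == pytest.approx(10.0)
    assert accuracy_by_density(90.0, 100.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        accuracy_by_density(10.0, 0.0)


def test_r_squared_closed_forms(rng):
    x = np.arange(10.0)
    assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)
    assert r_squared([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)
    xs = rng.uniform(0, 1, 30)
    ys = rng.uniform(0, 1, 30)
    perm = rng.permutation(30)
    assert r_squared(xs[perm], ys[perm]) == pytest.approx(r_squared(xs, ys))
    with pytest.raises(ValueError):
        r_squared([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        r_squared([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# matching invariants under generated configurations


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    truth=st.lists(
        st.tuples(st.floats(0, 99, allow_nan=False),
                  st.floats(0, 99, allow_nan=False)),
        min_size=0, max_size=12,
    ),
    det=st.lists(
        st.tuples(st.floats(0, 99, allow_nan=False),
                  st.floats(0, 99, allow_nan=False)),
        min_size=0, max_size=12,
    ),
    radius=st.floats(0.5, 30.0),
)
def test_matching_is_one_to_one_and_within_radius(truth, det, radius):
    truth = np.asarray(truth, float).reshape(-1, 2)
    det = np.asarray(det, float).reshape(-1, 2)
    m = match_detections(det, truth, radius)
    ts = [t for t, _ in m.pairs]
    ds = [d for _, d in m.pairs]
    assert len(set(ts)) == len(ts) and len(set(ds)) == len(ds)
    for t, d in m.pairs:
        assert np.linalg.norm(truth[t] - det[d]) <= radius + 1e-9
    assert len(m.pairs) + len(m.unmatched_truth) == len(truth)
    assert len(m.pairs) + len(m.unmatched_det) == len(det)
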