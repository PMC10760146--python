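"""Knot selection, geometric filters, and closed-spline fitting."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octlumen as ol
from octlumen.contour import DomainBins, EdgePoint, KnotSet
from octlumen.preprocess import EdgeMap

from conftest import random_knotset


def edge_map_from_pixels(pixels_xy, size=512, center=None):
    mask = np.zeros((size, size), dtype=bool)
    for x, y in pixels_xy:
        mask[y, x] = True
    return EdgeMap(mask=mask, mm_per_px=0.01,
                   catheter_center=center or ((size - 1) / 2, (size - 1) / 2))


def make_points(angle_radius_pairs):
    return [EdgePoint(angle_deg=a, radius_mm=r, source_pixel=(0, 0))
            for a, r in angle_radius_pairs]


# --- edge point collection --------------------------------------------------

def test_collect_axis_aligned_pixel():
    em = edge_map_from_pixels([(256 + 100, 256)], center=(256.0, 256.0))
    (p,) = ol.collect_edge_points(em)
    assert p.angle_deg == pytest.approx(0.0)
    assert p.radius_mm == pytest.approx(1.0)


def test_collect_flips_image_y_axis():
    """Pixel above the center (image y down) maps to physical angle 90."""
    em = edge_map_from_pixels([(256, 256 - 100)], center=(256.0, 256.0))
    (p,) = ol.collect_edge_points(em)
    assert p.angle_deg == pytest.approx(90.0)
    assert p.radius_mm == pytest.approx(1.0)


def test_collect_excludes_pixels_inside_center_mask():
    em = edge_map_from_pixels([(256 + 30, 256)], center=(256.0, 256.0))
    assert ol.collect_edge_points(em, mask_radius_mm=0.4) == []


def test_collect_empty_edge_map_is_empty_list():
    em = edge_map_from_pixels([])
    assert ol.collect_edge_points(em) == []


# --- domain binning ---------------------------------------------------------

def test_domain_boundary_is_half_open():
    cfg = ol.SegmentationConfig()
    bins = ol.bin_into_domains(make_points([(0.0, 1.0), (12.0, 1.0)]), cfg)
    assert len(bins.bins[0]) == 1 and len(bins.bins[1]) == 1


def test_last_domain_catches_high_angles():
    cfg = ol.SegmentationConfig()
    bins = ol.bin_into_domains(make_points([(359.9, 1.0)]), cfg)
    assert len(bins.bins[29]) == 1


@given(st.lists(st.tuples(st.floats(0, 359.999), st.floats(0.5, 3.0)), max_size=200))
@settings(deadline=None, max_examples=50)
def test_binning_is_a_partition(pairs):
    cfg = ol.SegmentationConfig()
    pts = make_points(pairs)
    bins = ol.bin_into_domains(pts, cfg)
    assert bins.n_domains == 30
    assert sum(len(b) for b in bins.bins) == len(pts)
    for i, b in enumerate(bins.bins):
        for p in b:
            assert i == int(p.angle_deg // 12.0)


# --- knot picking -----------------------------------------------------------

def test_pick_knot_is_minimum_radius():
    cfg = ol.SegmentationConfig()
    radii = [1.4, 1.2, 1.6, 1.3, 1.5, 1.7]
    pts = make_points([(1.0 + i, r) for i, r in enumerate(radii)])
    knots = ol.pick_knots(ol.bin_into_domains(pts, cfg), cfg)
    assert len(knots) == 1
    assert np.hypot(*knots.xy[0]) == pytest.approx(1.2)


def test_underpopulated_domain_emits_no_knot():
    cfg = ol.SegmentationConfig()
    pts = make_points([(1.0 + i, 1.5) for i in range(5)])  # 5 points < 6
    knots = ol.pick_knots(ol.bin_into_domains(pts, cfg), cfg)
    assert len(knots) == 0


def test_thirty_populated_domains_give_thirty_knots():
    cfg = ol.SegmentationConfig()
    pts = []
    for d in range(30):
        pts += make_points([(d * 12.0 + 1 + 0.1 * j, 1.5 + 0.01 * j) for j in range(6)])
    knots = ol.pick_knots(ol.bin_into_domains(pts, cfg), cfg)
    assert len(knots) == 30
    assert knots.provenance == tuple(range(30))
    assert np.all(np.diff(knots.angles_deg) > 0)


def test_radius_tie_breaks_to_smallest_angle():
    cfg = ol.SegmentationConfig()
    pts = make_points([(5.0 - 0.1 * j, 1.5) for j in range(6)])
    knots = ol.pick_knots(ol.bin_into_domains(pts, cfg), cfg)
    assert knots.angles_deg[0] == pytest.approx(4.5)


# --- spacing filter ---------------------------------------------------------

def spacing_oracle(xy, min_spacing):
    """Independent greedy cyclic fixpoint: drop the later of a violating pair."""
    pts = list(range(len(xy)))
    while len(pts) >= 2:
        n = len(pts)
        for j in range(n):
            a, b = pts[j], pts[(j + 1) % n]
            if a != b and np.hypot(*(xy[a] - xy[b])) < min_spacing:
                pts.remove(b)
                break
        else:
            break
    return pts


def test_close_pair_drops_later_knot():
    ks = KnotSet(xy=np.array([[1.5, 0.0], [1.5 * math.cos(0.06), 1.5 * math.sin(0.06)],
                              [0.0, 1.5], [-1.5, 0.0], [0.0, -1.5]]),
                 angles_deg=np.array([0.0, math.degrees(0.06), 90.0, 180.0, 270.0]))
    d01 = np.hypot(*(ks.xy[0] - ks.xy[1]))
    assert d01 < 0.25
    out = ol.enforce_spacing(ks, 0.25)
    assert len(out) == 4
    assert out.angles_deg[0] == 0.0  # earlier knot kept


def test_well_spaced_set_unchanged():
    ks = circle_knots(8, r=1.5)  # gaps ~1.15 mm >= 0.3
    gaps = np.hypot(*(ks.xy - np.roll(ks.xy, -1, axis=0)).T)
    assert gaps.min() >= 0.3
    out = ol.enforce_spacing(ks, 0.25)
    assert np.array_equal(out.xy, ks.xy)


def test_chain_of_close_knots_matches_greedy_oracle():
    # four knots each ~0.15 mm from the next along a small arc
    r = 1.5
    step = 0.15 / r
    angles = np.degrees(np.arange(4) * step)
    angles = np.append(angles, [120.0, 240.0])
    th = np.radians(angles)
    xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
    ks = KnotSet(xy=xy, angles_deg=angles)
    out = ol.enforce_spacing(ks, 0.25)
    expected = spacing_oracle(xy, 0.25)
    assert np.array_equal(out.xy, xy[expected])


def test_spacing_postcondition_on_random_sets():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        ks = random_knotset(rng)
        out = ol.enforce_spacing(ks, 0.25)
        expected = spacing_oracle(ks.xy, 0.25)
        assert np.array_equal(out.xy, ks.xy[expected])
        if len(out) >= 2:
            gaps = np.hypot(*(out.xy - np.roll(out.xy, -1, axis=0)).T)
            assert gaps.min() >= 0.25


# --- Menger curvature -------------------------------------------------------

def test_collinear_triple_has_zero_curvature():
    assert ol.menger_curvature((0, 0), (1, 0), (2, 0)) == 0.0


def test_circle_points_give_reciprocal_radius():
    r = 0.2
    p = [(r * math.cos(t), r * math.sin(t)) for t in (0.1, 1.0, 2.5)]
    assert ol.menger_curvature(*p) == pytest.approx(5.0, rel=1e-12)


def test_worked_triple_curvature():
    # circumcircle of (0,0), (1,1), (2,0) has radius 1
    assert ol.menger_curvature((0, 0), (1, 1), (2, 0)) == pytest.approx(1.0)


def test_coincident_points_rejected():
    with pytest.raises(ValueError, match="distinct"):
        ol.menger_curvature((0, 0), (0, 0), (1, 1))


@given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0.1, 10),
       st.floats(0, 2 * math.pi))
@settings(deadline=None, max_examples=50)
def test_curvature_rigid_invariance_and_scaling(tx, ty, s, rot):
    pts = np.array([[0.3, 0.1], [0.9, 0.8], [1.7, 0.2]])
    k0 = ol.menger_curvature(*pts)
    c, sn = math.cos(rot), math.sin(rot)
    R = np.array([[c, -sn], [sn, c]])
    moved = pts @ R.T + [tx, ty]
    assert ol.menger_curvature(*moved) == pytest.approx(k0, rel=1e-9)
    assert ol.menger_curvature(*(pts * s)) == pytest.approx(k0 / s, rel=1e-9)


# --- curvature pruning ------------------------------------------------------

def circle_knots(n, r=1.5, spike=None):
    angles = np.arange(n) * 360.0 / n + 1.0
    th = np.radians(angles)
    radii = np.full(n, float(r))
    if spike is not None:
        idx, rad = spike
        radii[idx] = rad
    xy = np.column_stack([radii * np.cos(th), radii * np.sin(th)])
    return KnotSet(xy=xy, angles_deg=angles)


def prune_oracle(xy, max_k, min_n):
    """Independent fixpoint: recompute all curvatures, remove worst, repeat."""
    def kappa(a, b, c):
        ab, bc, ac = (np.linalg.norm(b - a), np.linalg.norm(c - b),
                      np.linalg.norm(c - a))
        area2 = abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])
        return 2 * area2 / (ab * bc * ac)

    keep = list(range(len(xy)))
    while True:
        ks = [kappa(xy[keep[i - 1]], xy[keep[i]], xy[keep[(i + 1) % len(keep)]])
              for i in range(len(keep))]
        worst = int(np.argmax(ks))
        if ks[worst] <= max_k:
            return keep, False
        if len(keep) <= min_n:
            return keep, True
        del keep[worst]


def test_low_curvature_circle_unchanged():
    ks = circle_knots(12, r=1.5)  # kappa ~ 0.67
    out, flagged = ol.prune_curvature(ks, 5.0)
    assert not flagged and len(out) == 12


def test_single_spike_removed():
    # 60 knots: neighbor chord ~0.31 mm, so a spike above 5 mm^-1 is attainable
    ks = circle_knots(60, r=1.5, spike=(5, 1.35))
    from octlumen.contour import _all_curvatures

    assert _all_curvatures(ks.xy).max() > 5.0
    out, flagged = ol.prune_curvature(ks, 5.0)
    assert not flagged
    assert len(out) == 59
    assert _all_curvatures(out.xy).max() <= 5.0


def test_multi_spike_matches_iterative_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(30, 60))
        ks = circle_knots(n, r=float(rng.uniform(1.0, 2.0)))
        xy = ks.xy.copy()
        for idx in rng.choice(n, size=3, replace=False):
            xy[idx] *= rng.uniform(0.75, 0.95)
        ks = KnotSet(xy=xy, angles_deg=ks.angles_deg)
        out, flagged = ol.prune_curvature(ks, 5.0, min_knots=4)
        keep, oflag = prune_oracle(xy, 5.0, 4)
        assert flagged == oflag
        assert np.array_equal(out.xy, xy[keep])


def test_too_few_knots_rejected():
    ks = circle_knots(12).subset([0, 1])
    with pytest.raises(ValueError):
        ol.prune_curvature(ks, 5.0)


# --- closed-curve fitting ---------------------------------------------------

def test_circle_fit_has_small_radial_deviation():
    ks = circle_knots(12, r=1.5)
    contour = ol.fit_closed_curve(ks)
    r = np.hypot(*contour.sample(2000).T)
    assert np.abs(r - 1.5).max() < 0.01


def test_curve_interpolates_every_knot():
    ks = random_knotset(np.random.default_rng(8), n=15, r_range=(1.5, 2.5))
    contour = ol.fit_closed_curve(ks)
    pts = contour.evaluate(contour.knot_params[:-1])
    assert np.abs(pts - ks.xy).max() < 1e-6


def test_curve_is_closed():
    ks = circle_knots(10)
    contour = ol.fit_closed_curve(ks)
    assert np.allclose(contour.evaluate(0.0), contour.evaluate(1.0), atol=1e-9)


def test_unit_weights_nurbs_representation():
    contour = ol.fit_closed_curve(circle_knots(10))
    assert contour.degree == 3
    assert np.all(contour.weights == 1.0)
    assert np.all(np.diff(contour.knot_vector) >= 0)


def test_too_few_knots_flagged_unsegmentable():
    ks = circle_knots(12).subset([0, 3, 6])
    with pytest.raises(ol.UnsegmentableFrame):
        ol.fit_closed_curve(ks, min_knots_for_fit=4)


# --- full frame segmentation ------------------------------------------------

def test_segment_clean_circle_recovers_area(circle_frame, circle_contour):
    _, gt = circle_frame
    m = ol.frame_metrics(circle_contour)
    assert m.area == pytest.approx(gt.area, rel=0.02)


def test_segment_bridges_guidewire_shadow():
    spec = ol.PhantomSpec(shape=ol.Circle(1.5), shadow_wedges=((40.0, 12.0),), seed=2)
    f, gt = ol.synth_frame(spec)
    contour, diag = ol.segment_frame(f)
    assert contour is not None
    m = ol.frame_metrics(contour)
    assert m.area == pytest.approx(gt.area, rel=0.05)
    assert np.allclose(contour.evaluate(0.0), contour.evaluate(1.0), atol=1e-9)


def test_segment_all_dark_frame_is_flagged():
    f = ol.FrameImage(pixels=np.full((128, 128), 10, dtype=np.uint8),
                      mm_per_px=0.01, catheter_center=(63.5, 63.5))
    contour, diag = ol.segment_frame(f)
    assert contour is None and diag.unsegmentable


def test_rotating_phantom_rotates_knots_and_preserves_metrics():
    """12-degree-multiple feature rotation: equivariant knots, stable metrics."""
    shape = ol.FourierShape(1.6, ((2, 0.12, 0.3),))
    d = math.radians(24.0)
    rotated = ol.FourierShape(1.6, tuple((k, a, p - k * d) for k, a, p in shape.harmonics))
    c1, _ = ol.segment_frame(ol.synth_frame(
        ol.PhantomSpec(shape=shape, speckle_scale=0.0))[0])
    c2, _ = ol.segment_frame(ol.synth_frame(
        ol.PhantomSpec(shape=rotated, speckle_scale=0.0))[0])
    m1, m2 = ol.frame_metrics(c1), ol.frame_metrics(c2)
    assert m2.area == pytest.approx(m1.area, rel=0.01)
    assert m2.d_mean == pytest.approx(m1.d_mean, rel=0.01)
    a1 = np.sort(np.degrees(np.arctan2(c1.knot_points[:, 1], c1.knot_points[:, 0])) % 360)
    a2 = np.sort((np.degrees(np.arctan2(c2.knot_points[:, 1], c2.knot_points[:, 0])) - 24) % 360)
    assert len(a1) == len(a2)
    # correspondence at domain granularity (rasterization moves ties within a domain)
    diffs = np.abs(a1 - a2)
    assert np.minimum(diffs, 360 - diffs).max() <= 12.0


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        ol.SegmentationConfig(n_domains=31)
    with pytest.raises(ValueError):
        ol.SegmentationConfig(min_knot_spacing_mm=0.0)
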