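"""Substrate architecture models: dimensions, depth profiles, groove truth."""

import numpy as np
import pytest

from angioarch.geometry import (
    DESIGN_NAMES,
    GrooveSet,
    depth_profile,
    designs_from_config,
    groove_truth,
    make_design,
)

NONFLAT = [n for n in DESIGN_NAMES if n != "flat"]


@pytest.mark.parametrize(
    "name, width, periodicity, depth, polarity",
    [
        ("large", 660, 1240, 300, "concave"),
        ("large_deep", 660, 1240, 585, "concave"),
        ("large_convex", 660, 1240, 300, "convex"),
        ("small", 330, 630, 150, "concave"),
        ("small_deep", 330, 630, 300, "concave"),
        ("small_convex", 330, 630, 150, "convex"),
        ("flat", 0, 0, 0, "flat"),
    ],
)
def test_measured_dimensions(name, width, periodicity, depth, polarity):
    d = make_design(name)
    assert (d.feature_width, d.periodicity, d.depth, d.polarity) == (
        width, periodicity, depth, polarity,
    )


def test_unknown_design_lists_valid_names():
    with pytest.raises(ValueError, match="large_deep"):
        make_design("zigzag")


def test_flat_profile_is_zero_everywhere():
    prof = depth_profile(make_design("flat"), 5740.0, 2.0)
    assert np.all(prof.z == 0)


def test_large_groove_center_depth():
    # phase 0 centres the first groove at x = 620; midpoint between
    # grooves is a ridge top
    prof = depth_profile(make_design("large"), 5740.0, 2.0)
    z_at = lambda x: prof.z[np.argmin(np.abs(prof.x - x))]
    assert z_at(620.0) == pytest.approx(300.0, abs=0.5)
    assert z_at(1240.0) == 0.0


def test_large_deep_is_semicircle_plus_wall():
    # total 585 um = 330 um semicircular arc + 255 um vertical wall
    prof = depth_profile(make_design("large_deep"), 1240.0, 0.5)
    z_at = lambda x: prof.z[np.argmin(np.abs(prof.x - x))]
    assert z_at(620.0) == pytest.approx(585.0, abs=0.5)
    # the arc contributes exactly its 330-um radius above the wall, and
    # just outside the groove edge the surface is the ridge plane
    assert z_at(620.0) - 330.0 == pytest.approx(255.0, abs=0.5)
    assert z_at(620.0 - 331.0) == 0.0


def test_undersampled_geometry_rejected():
    with pytest.raises(ValueError, match="undersample"):
        depth_profile(make_design("small"), 1000.0, sampling=100.0)


@pytest.mark.parametrize("name", NONFLAT)
def test_profile_periodicity_and_max_depth(name):
    d = make_design(name)
    prof = depth_profile(d, 3 * d.periodicity, 1.0, phase=37.0)
    period_px = int(round(d.periodicity / 1.0))
    assert np.allclose(prof.z[:period_px], prof.z[period_px : 2 * period_px],
                       atol=1e-6)
    assert prof.z.max() == pytest.approx(d.depth, abs=0.5)


def test_groove_truth_flat_is_empty():
    gs = groove_truth(make_design("flat"), 5740.0)
    assert gs.n_grooves == 0 and gs.extent == 5740.0
    assert gs.outside_length == 5740.0


def test_groove_truth_large_layout():
    gs = groove_truth(make_design("large"), 5740.0)
    widths = gs.intervals[:, 1] - gs.intervals[:, 0]
    # four complete 660-um intervals repeating every 1240 um, plus the
    # clipped partial at the boundary
    assert gs.intervals[0, 0] == pytest.approx(290.0)
    assert np.allclose(widths[:4], 660.0)
    assert np.allclose(np.diff(gs.intervals[:4, 0]), 1240.0)
    assert gs.intervals[-1, 1] == pytest.approx(5740.0)


def test_groove_truth_small_convex_complement():
    gs = groove_truth(make_design("small_convex"), 630.0)
    assert np.allclose(gs.intervals, [[0.0, 150.0], [480.0, 630.0]])


@pytest.mark.parametrize("name", NONFLAT)
def test_groove_truth_matches_depth_profile_scan(name):
    """Brute-force oracle: grooves are where z > 0 (concave) or the
    complement of the bump spans (convex)."""
    d = make_design(name)
    extent, dx = 5740.0, 0.5
    prof = depth_profile(d, extent, dx, phase=0.0)
    gs = groove_truth(d, extent, phase=0.0)
    if d.polarity == "concave":
        inside_scan = prof.z > 1e-9
    else:
        inside_scan = prof.z >= d.depth - 1e-9
        # convex flats are exactly at depth; bump spans are below
    inside_truth = gs.contains(prof.x)
    # agreement everywhere except within one sample of interval edges
    disagree = prof.x[inside_scan != inside_truth]
    edges = gs.intervals.ravel()
    if disagree.size:
        dist = np.min(np.abs(disagree[:, None] - edges[None, :]), axis=1)
        assert dist.max() <= 2 * dx


@pytest.mark.parametrize("name", NONFLAT)
def test_groove_and_outside_tile_extent(name):
    gs = groove_truth(make_design(name), 5740.0, phase=123.0)
    assert gs.groove_length + gs.outside_length == pytest.approx(5740.0)


def test_phase_shifts_intervals():
    d = make_design("small")
    delta = 77.0
    a = groove_truth(d, 2 * d.periodicity, phase=0.0)
    b = groove_truth(d, 2 * d.periodicity, phase=delta)
    # complete intervals shift by delta (wrap effects only at the boundary)
    full_a = [iv for iv in a.intervals if iv[1] - iv[0] > d.feature_width - 1]
    for s, e in full_a:
        if e + delta <= 2 * d.periodicity:
            assert np.any(np.isclose(b.intervals[:, 0], s + delta, atol=1e-6))


def test_grooveset_invariants_enforced():
    with pytest.raises(ValueError):
        GrooveSet(np.array([[10.0, 5.0]]), 100.0)  # start >= end
    with pytest.raises(ValueError):
        GrooveSet(np.array([[0.0, 50.0], [40.0, 80.0]]), 100.0)  # overlap


def test_designs_from_config_parses_blocks():
    text = """
name: wavy
feature_width: 200
periodicity: 500
depth: 100
polarity: concave
"""
    d = designs_from_config(text)["wavy"]
    assert d.feature_width == 200 and d.polarity == "concave"
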