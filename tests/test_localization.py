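"""Groove detection from depth profiles and the degree of containment."""

import numpy as np
import pytest

from angioarch.geometry import (
    DepthProfile,
    GrooveSet,
    depth_profile,
    groove_truth,
    make_design,
)
from angioarch.localization import (
    GrooveJParams,
    SignalProfile,
    degree_of_containment,
    depth_profile_from_stack,
    detect_grooves,
    vertical_signal_profile,
)
from angioarch.synthetic import (
    BinaryMask,
    ImageStack,
    generate_coculture_stack,
)

NONFLAT = ["large", "large_deep", "large_convex", "small", "small_deep",
           "small_convex"]


def test_groovej_param_validation():
    p = GrooveJParams()
    assert (p.line_width, p.rolling_z_window) == (300.0, 100.0)
    assert (p.z_threshold, p.slope_factor, p.curvature, p.depth_weighting) == (
        0.5, 0.35, 0.4, 0.01,
    )
    with pytest.raises(ValueError):
        GrooveJParams(z_threshold=0.0)
    with pytest.raises(ValueError):
        GrooveJParams(line_width=-1)


@pytest.mark.parametrize("name", NONFLAT)
def test_detect_grooves_recovers_analytic_profiles(name):
    """Groove counts match ground truth and centres land within 30 um."""
    design = make_design(name)
    prof = depth_profile(design, 5740.0, 2.0)
    truth = groove_truth(design, 5740.0)
    det = detect_grooves(prof)
    assert det.n_grooves == truth.n_grooves
    assert np.abs(det.centers() - truth.centers()).max() <= 30.0


@pytest.mark.parametrize("name", ["large", "small_convex"])
def test_detected_widths_close_to_truth(name):
    design = make_design(name)
    det = detect_grooves(depth_profile(design, 5740.0, 2.0))
    truth = groove_truth(design, 5740.0)
    w_det = det.intervals[:, 1] - det.intervals[:, 0]
    w_tru = truth.intervals[:, 1] - truth.intervals[:, 0]
    assert np.all(np.abs(w_det - w_tru) / w_tru <= 0.15)


def test_flat_profile_yields_empty_set():
    x = np.arange(0.0, 1000.0, 2.0)
    det = detect_grooves(DepthProfile(x, np.zeros_like(x)))
    assert det.n_grooves == 0


def test_short_profile_rejected():
    x = np.arange(0.0, 150.0, 2.0)
    with pytest.raises(ValueError, match="extent"):
        detect_grooves(DepthProfile(x, np.abs(np.sin(x))))


def test_depth_recovery_from_synthetic_stack():
    """Stack-measured depth at complete groove centres within 0.6 x
    z-spacing of the 300-um design depth."""
    design = make_design("large")
    stack, _ = generate_coculture_stack(
        design, n_filaments=40, alignment_kappa=4.0, containment_prob=1.0,
        image_size_px=(1200, 1050), seed=7,
    )
    prof = depth_profile_from_stack(stack)
    truth = groove_truth(design, prof.extent)
    complete = [iv for iv in truth.intervals
                if iv[1] - iv[0] >= design.feature_width - 1]
    assert complete
    for s, e in complete:
        c = (s + e) / 2
        z = prof.z[np.argmin(np.abs(prof.x - c))]
        assert z == pytest.approx(300.0, abs=0.6 * stack.z_spacing)


def test_single_slice_stack_gives_flat_profile():
    stack = ImageStack(np.random.default_rng(0).uniform(0, 1, (1, 200, 300)),
                       2.3917, 10.0)
    prof = depth_profile_from_stack(stack)
    assert np.all(prof.z == 0)


def test_flat_design_stack_profile_is_flat():
    stack, _ = generate_coculture_stack(
        make_design("flat"), n_filaments=40, alignment_kappa=0.0,
        containment_prob=0.0, image_size_px=(1200, 1050), seed=3,
    )
    prof = depth_profile_from_stack(stack)
    assert prof.z.std() < stack.z_spacing
    assert detect_grooves(prof).n_grooves == 0


# --- vertical signal profile ---------------------------------------------

def test_vertical_profile_trivial_masks():
    full = BinaryMask(np.ones((10, 20), bool), 2.0)
    assert np.all(vertical_signal_profile(full).value == 1.0)
    single = np.zeros((10, 20), bool)
    single[:, 7] = True
    prof = vertical_signal_profile(BinaryMask(single, 2.0))
    assert prof.value[7] == 1.0 and prof.value.sum() == 1.0


def test_containment_run_concentrates_profile_mass():
    design = make_design("large")
    stack, _ = generate_coculture_stack(
        design, n_filaments=40, alignment_kappa=4.0, containment_prob=1.0,
        image_size_px=(1200, 1050), seed=11,
    )
    from angioarch.preprocess import (autocontrast_to_8bit,
                                      filter_small_particles, max_projection,
                                      phansalkar_mask, rolling_ball_subtract)

    sub = rolling_ball_subtract(max_projection(stack), 50.0)
    mask = filter_small_particles(phansalkar_mask(autocontrast_to_8bit(sub)))
    prof = vertical_signal_profile(mask)
    inside = groove_truth(design, prof.extent).contains(prof.x)
    assert prof.value[inside].sum() / prof.value.sum() >= 0.80


# --- degree of containment -------------------------------------------------

def test_constant_profile_gives_exact_unit_doc():
    x = np.arange(0.0, 5740.0, 2.0)
    grooves = groove_truth(make_design("large"), 5740.0)
    res = degree_of_containment(SignalProfile(x, np.full_like(x, 1.0)), grooves)
    assert res.doc == 1.0
    res2 = degree_of_containment(SignalProfile(x, np.full_like(x, 0.37)),
                                 grooves)
    assert res2.doc == pytest.approx(1.0, abs=1e-12)


def test_doc_arithmetic_example():
    # grooves spanning 2000 um holding signal 300; outside 3740 um
    # holding 187 -> doc = (300/2000) / (187/3740) = 3
    dx = 1.0
    x = np.arange(0.0, 5740.0, dx)
    vals = np.where(x < 2000.0, 300.0 / 2000.0, 187.0 / 3740.0)
    prof = SignalProfile(x, vals)
    grooves = GrooveSet(np.array([[0.0, 2000.0]]), 5740.0)
    res = degree_of_containment(prof, grooves)
    assert res.doc == pytest.approx(3.0, rel=1e-9)
    assert res.groove_length == pytest.approx(2000.0)


def test_doc_all_signal_inside_is_infinite_sentinel():
    x = np.arange(0.0, 1000.0, 2.0)
    vals = np.where(x < 500.0, 1.0, 0.0)
    res = degree_of_containment(SignalProfile(x, vals),
                                GrooveSet(np.array([[0.0, 500.0]]), 1000.0))
    assert res.doc == np.inf and not res.undefined


def test_doc_without_grooves_is_undefined():
    x = np.arange(0.0, 1000.0, 2.0)
    res = degree_of_containment(SignalProfile(x, np.ones_like(x)),
                                GrooveSet(np.empty((0, 2)), 1000.0))
    assert res.undefined


def test_doc_scale_invariance():
    rng = np.random.default_rng(5)
    x = np.arange(0.0, 2000.0, 2.0)
    vals = rng.uniform(0, 1, x.size)
    grooves = GrooveSet(np.array([[100.0, 700.0], [1200.0, 1600.0]]), 2000.0)
    a = degree_of_containment(SignalProfile(x, vals), grooves).doc
    b = degree_of_containment(SignalProfile(x, 9.0 * vals), grooves).doc
    assert a == pytest.approx(b, rel=1e-12)


def test_doc_extent_mismatch_rejected():
    x = np.arange(0.0, 1000.0, 2.0)
    with pytest.raises(ValueError, match="extent"):
        degree_of_containment(SignalProfile(x, np.ones_like(x)),
                              GrooveSet(np.array([[0.0, 100.0]]), 2000.0))
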