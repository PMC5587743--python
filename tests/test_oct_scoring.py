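"""OCT scoring: catheter scale, ROI geometry, segmentation accuracy
against renderer truth, ORI closed forms, thickness statistics and the
ICRS decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cartinirs import oct_scoring as oct
from cartinirs import synthetic_data as sd


def _phantom(grade, seed, **kwargs):
    rng = np.random.default_rng(seed)
    truth = sd.sample_composition(grade, rng)
    lesion = sd.sample_lesion(grade, rng)
    return sd.make_bscan(lesion, truth, rng, **kwargs), lesion


# --------------------------------------------------------------------- catheter


def test_catheter_scale_within_two_percent():
    (bscan, gt), _ = _phantom(0, 21)
    det = oct.detect_catheter(bscan)
    assert det.px_per_mm == pytest.approx(250.0, rel=0.02)


def test_catheter_absent_raises(rng):
    blank = oct.BScan(rng.exponential(0.02, (512, 512)))
    with pytest.raises(oct.CatheterNotFoundError):
        oct.detect_catheter(blank)


def test_catheter_translation_invariance():
    rng1 = np.random.default_rng(33)
    truth = sd.sample_composition(0, rng1)
    lesion = sd.sample_lesion(0, rng1)
    scales = []
    for center in [(140.0, 400.0), (170.0, 650.0)]:
        rng = np.random.default_rng(33)
        b, _ = sd.make_bscan(lesion, truth, rng, catheter_center=center)
        scales.append(oct.detect_catheter(b).px_per_mm)
    assert scales[0] == pytest.approx(scales[1], rel=0.005)


# --------------------------------------------------------------------- ROI


def test_roi_centered_2mm_window():
    (bscan, _), _ = _phantom(0, 5)
    assert oct.select_roi(bscan, px_per_mm=250.0) == (262, 762)


def test_roi_narrow_field_of_view_rejected(rng):
    small = oct.BScan(rng.exponential(0.02, (256, 300)))
    with pytest.raises(oct.ScoringError):
        oct.select_roi(small, px_per_mm=250.0)


def test_roi_off_center_shifts_window():
    (bscan, _), _ = _phantom(0, 5)
    a, b = oct.select_roi(bscan, px_per_mm=250.0, center_col=600)
    assert (a, b) == (350, 850)
    assert b - a == 500


# --------------------------------------------------------------------- surface


def test_surface_flat_noiseless_subpixel():
    """On a noiseless flat phantom the detected line sits within half an
    axial pixel of the rendered surface."""
    rng = np.random.default_rng(8)
    lesion = sd.LesionSpec(0.0, 700.0, 0.0, 800.0, 0.0)
    bscan, gt = sd.make_bscan(
        lesion, None, rng, surface_modulation_um=np.zeros(1024),
        surface_depth_um=1600.0, speckle=False, catheter_center=(130.0, 130.0),
    )
    roi = (262, 762)
    surf = oct.detect_surface(bscan, roi, px_per_mm=250.0)
    assert np.all(np.abs(surf - gt.surface_um[262:762]) <= 2.0 + 1e-6)


def test_surface_accuracy_over_seeded_phantoms():
    """Mean |detected - truth| stays below one pixel over 50 speckled
    phantoms of grades 0-2."""
    errs = []
    for i in range(50):
        (bscan, gt), _ = _phantom(i % 3, 100 + i)
        det = oct.detect_catheter(bscan)
        roi = oct.select_roi(bscan, det.px_per_mm)
        surf = oct.detect_surface(bscan, roi, catheter=det, px_per_mm=det.px_per_mm)
        errs.append(np.mean(np.abs(surf - gt.surface_um[roi[0] : roi[1]])))
    assert np.mean(errs) <= 4.0  # 1 px at 4 um/px


def test_surface_blank_image_fails(rng):
    blank = oct.BScan(rng.exponential(0.02, (1024, 1024)) + rng.normal(0.012, 0.004, (1024, 1024)).clip(0))
    with pytest.raises(oct.SurfaceNotFoundError):
        oct.detect_surface(blank, (262, 762), px_per_mm=250.0)


# --------------------------------------------------------------------- interface


def test_interface_accuracy_over_seeded_phantoms():
    """Mean |detected - truth| stays below two pixels over 50 phantoms."""
    errs = []
    for i in range(50):
        (bscan, gt), _ = _phantom(i % 3, 300 + i)
        det = oct.detect_catheter(bscan)
        roi = oct.select_roi(bscan, det.px_per_mm)
        surf = oct.detect_surface(bscan, roi, catheter=det, px_per_mm=det.px_per_mm)
        iface = oct.detect_interface(bscan, roi, surf, det.px_per_mm)
        assert iface is not None
        errs.append(np.mean(np.abs(iface - gt.interface_um[roi[0] : roi[1]])))
    assert np.mean(errs) <= 8.0  # 2 px at 4 um/px


def test_interface_never_above_surface():
    (bscan, _), _ = _phantom(2, 77)
    det = oct.detect_catheter(bscan)
    roi = oct.select_roi(bscan, det.px_per_mm)
    surf = oct.detect_surface(bscan, roi, catheter=det, px_per_mm=det.px_per_mm)
    iface = oct.detect_interface(bscan, roi, surf, det.px_per_mm)
    assert np.all(iface >= surf)


def test_interface_at_image_bottom_not_found(rng):
    """An interface rendered off the bottom edge yields a clean not-found
    signal rather than a crash."""
    lesion = sd.LesionSpec(2.0, 3000.0, 0.0, 800.0, 0.0)
    geo = sd.BScanGeometry()
    bscan, _ = sd.make_bscan(
        lesion, None, rng, geometry=geo, surface_depth_um=1600.0,
        surface_modulation_um=np.zeros(1024),
    )
    roi = (262, 762)
    surf = oct.detect_surface(bscan, roi, px_per_mm=250.0)
    assert oct.detect_interface(bscan, roi, surf, 250.0) is None


# --------------------------------------------------------------------- ORI


def test_ori_flat_and_tilted_zero():
    x = np.arange(500, dtype=float)
    assert oct.compute_ori(np.full(500, 400.0)) == pytest.approx(0.0, abs=1e-9)
    assert oct.compute_ori(400.0 + 0.3 * x) == pytest.approx(0.0, abs=1e-9)


def test_ori_sinusoid_closed_form():
    x = np.arange(500, dtype=float)
    surf = 400.0 + 12.0 * np.sin(2 * np.pi * x / 50.0)
    assert oct.compute_ori(surf) == pytest.approx(12.0 / np.sqrt(2), rel=0.02)


def test_ori_gaussian_perturbation_converges_to_sigma():
    """Monte-Carlo: ORI of a line plus N(0, sigma^2) noise approaches
    sigma as the column count grows."""
    rng = np.random.default_rng(9)
    sigma = 5.0
    oris = [
        oct.compute_ori(100.0 + 0.1 * np.arange(5000) + rng.normal(0, sigma, 5000))
        for _ in range(20)
    ]
    assert np.mean(oris) == pytest.approx(sigma, rel=0.03)


def test_ori_too_few_columns_rejected():
    with pytest.raises(oct.ScoringError):
        oct.compute_ori(np.full(5, 100.0))


@settings(max_examples=25, deadline=None)
@given(
    offset=st.floats(-500, 500, allow_nan=False),
    slope=st.floats(-2, 2, allow_nan=False),
)
def test_ori_invariant_to_offset_and_tilt(offset, slope):
    rng = np.random.default_rng(4)
    base = rng.normal(400.0, 10.0, 300)
    x = np.arange(300, dtype=float)
    a = oct.compute_ori(base)
    b = oct.compute_ori(base + offset + slope * x)
    assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


# --------------------------------------------------------------------- thickness / grading


def test_thickness_uniform_phantom():
    (bscan, gt), lesion = _phantom(0, 55)
    score = oct.score_bscan(bscan)
    assert score.mean_thickness == pytest.approx(lesion.thickness_nominal, abs=8.0)
    assert score.loss_fraction < 0.05


def test_thickness_sixty_percent_defect():
    rng = np.random.default_rng(66)
    lesion = sd.LesionSpec(3.0, 700.0, 0.60, 900.0, 0.0)
    bscan, _ = sd.make_bscan(lesion, None, rng)
    score = oct.score_bscan(bscan)
    assert score.max_defect_fraction == pytest.approx(0.60, abs=0.04)
    assert score.grade == 3


def test_bone_exposure_detected():
    rng = np.random.default_rng(67)
    lesion = sd.LesionSpec(3.0, 700.0, 1.0, 900.0, 0.0)
    bscan, _ = sd.make_bscan(lesion, None, rng)
    score = oct.score_bscan(bscan)
    assert score.bone_exposed and score.grade == 4


def test_assign_icrs_decision_tree():
    cases = [
        ((5.0, 0.02, 0.02, False), 0),
        ((12.0, 0.05, 0.05, False), 1),
        ((12.0, 0.12, 0.12, False), 2),
        ((12.0, 0.62, 0.62, False), 3),
        ((12.0, 1.0, 1.0, True), 4),
    ]
    for args, want in cases:
        assert oct.assign_icrs(*args) == want


@settings(max_examples=50, deadline=None)
@given(
    ori=st.floats(0, 40, allow_nan=False),
    loss=st.floats(0, 1, allow_nan=False),
    defect=st.floats(0, 1, allow_nan=False),
    bone=st.booleans(),
    bump=st.floats(0, 10, allow_nan=False),
)
def test_grade_monotone_in_each_input(ori, loss, defect, bone, bump):
    g0 = oct.assign_icrs(ori, loss, defect, bone)
    assert oct.assign_icrs(ori + bump, loss, defect, bone) >= g0
    assert oct.assign_icrs(ori, min(loss + bump / 10, 1.0), defect, bone) >= g0
    assert oct.assign_icrs(ori, loss, min(defect + bump / 10, 1.0), bone) >= g0


def test_score_bscan_deterministic():
    (bscan, _), _ = _phantom(1, 88)
    s1, s2 = oct.score_bscan(bscan), oct.score_bscan(bscan)
    assert s1.to_dict() == s2.to_dict()


def test_grade0_ori_mass_below_threshold():
    oris = []
    for i in range(12):
        (bscan, _), _ = _phantom(0, 500 + i)
        oris.append(oct.score_bscan(bscan).ori)
    assert np.all(np.array(oris) < 8.0)
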