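"""Disc-summation volumetrics against analytic shapes and voxel counting."""

import numpy as np
import pytest

from scarchar.errors import ContainmentError, DomainError, GeometryError
from scarchar.io_formats import ContourSet, SliceContours, polygon_mask
from scarchar.volumetrics import (
    body_surface_area,
    cavity_volume,
    compute_volumetrics,
    ejection_fraction,
    index_to_bsa,
    myocardial_mass,
    polygon_area_mm2,
)

from conftest import circle


def _stack_of(polys, key="endocardium", **extra):
    cs = ContourSet()
    for i, p in enumerate(polys):
        kwargs = {key: p}
        kwargs.update({k: v[i] for k, v in extra.items()})
        cs.slices[i] = SliceContours(**kwargs)
    return cs


def test_cylinder_volume_analytic():
    """One circular endo contour r=10 mm, 10 mm slice: pi r^2 h = 3.1416 ml."""
    cs = _stack_of([circle(0, 0, 10.0, n=720)])
    v = cavity_volume(cs, slice_thickness_mm=10.0)
    assert v == pytest.approx(np.pi * 100 * 10 / 1000.0, rel=1e-4)


def test_volume_linear_in_slice_count():
    poly = circle(0, 0, 10.0, n=720)
    v1 = cavity_volume(_stack_of([poly]), 10.0)
    v5 = cavity_volume(_stack_of([poly] * 5), 10.0)
    assert v5 == pytest.approx(5 * v1, rel=1e-12)


def test_slice_gap_enters_disc_height():
    poly = circle(0, 0, 10.0, n=720)
    v = cavity_volume(_stack_of([poly]), 8.0, slice_gap_mm=2.0)
    assert v == pytest.approx(cavity_volume(_stack_of([poly]), 10.0), rel=1e-12)


def test_annulus_mass_analytic():
    """Epi r=20, endo r=10, one 10 mm slice: 9.424 ml wall x 1.05 = 9.896 g."""
    cs = _stack_of([circle(0, 0, 20.0, n=1440)], key="epicardium")
    cs.slices[0].endocardium = circle(0, 0, 10.0, n=1440)
    m = myocardial_mass(cs, 10.0)
    expected = (np.pi * 400 - np.pi * 100) * 10 / 1000.0 * 1.05
    assert m == pytest.approx(expected, rel=1e-4)


def test_epi_equals_endo_gives_zero_mass():
    poly = circle(0, 0, 15.0, n=720)
    cs = _stack_of([poly], key="epicardium")
    cs.slices[0].endocardium = poly.copy()
    assert myocardial_mass(cs, 10.0) == pytest.approx(0.0, abs=1e-12)


def test_endo_larger_than_epi_rejected():
    cs = _stack_of([circle(0, 0, 10.0)], key="epicardium")
    cs.slices[0].endocardium = circle(0, 0, 12.0)
    with pytest.raises(ContainmentError):
        myocardial_mass(cs, 10.0)


def test_self_intersecting_contour_rejected():
    bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
    with pytest.raises(GeometryError):
        cavity_volume(_stack_of([bowtie]), 10.0)


def test_irregular_polygon_matches_voxel_count_oracle():
    """Disc summation vs rasterize-and-count on a jagged polygon, within one
    boundary voxel layer (perimeter x spacing x thickness)."""
    rng = np.random.default_rng(2)
    t = np.sort(rng.uniform(0, 2 * np.pi, 24))
    r = rng.uniform(8.0, 14.0, t.size)
    poly = np.column_stack([40 + r * np.cos(t), 40 + r * np.sin(t)])
    thickness, spacing = 10.0, 0.5
    v_disc = cavity_volume(_stack_of([poly]), thickness)
    mask = polygon_mask(poly, (160, 160), (spacing, spacing))
    v_vox = mask.sum() * spacing * spacing * thickness / 1000.0
    perimeter = np.sum(np.hypot(*(np.diff(np.vstack([poly, poly[:1]]), axis=0).T)))
    tol_ml = perimeter * spacing * thickness / 1000.0
    assert abs(v_disc - v_vox) <= tol_ml


def test_phantom_mass_matches_truth_voxel_volume(default_phantom):
    stack, truth = default_phantom
    m = myocardial_mass(truth.contours, stack.slice_thickness_mm)
    voxel_ml = (stack.pixel_spacing_mm[0] * stack.pixel_spacing_mm[1]
                * stack.slice_thickness_mm / 1000.0)
    m_vox = truth.myocardium_mask.sum() * voxel_ml * 1.05
    # boundary band: one voxel layer along endo+epi circumference per slice
    per_slice_band = (
        2 * np.pi * (20.0 + 30.0) * stack.pixel_spacing_mm[0]
        * stack.slice_thickness_mm / 1000.0 * 1.05
    )
    assert abs(m - m_vox) <= stack.n_slices * per_slice_band


def test_volume_invariant_under_rotation_translation():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 2 * np.pi, 18))
    r = rng.uniform(8, 13, t.size)
    poly = np.column_stack([r * np.cos(t), r * np.sin(t)])
    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = poly @ rot.T + np.array([25.0, -12.0])
    v0 = cavity_volume(_stack_of([poly]), 10.0)
    v1 = cavity_volume(_stack_of([moved]), 10.0)
    assert v1 == pytest.approx(v0, rel=1e-9)
    scaled = poly * 1.5
    assert cavity_volume(_stack_of([scaled]), 10.0) == pytest.approx(
        v0 * 1.5**2, rel=1e-9
    )


def test_ejection_fraction_identities():
    assert ejection_fraction(100.0, 100.0) == 0.0
    assert ejection_fraction(100.0, 0.0) == 100.0
    assert ejection_fraction(284.0, 222.0) == pytest.approx(21.83, abs=0.01)
    with pytest.raises(DomainError):
        ejection_fraction(0.0, 0.0)


def test_bsa_mosteller_exact_and_dubois_close():
    assert body_surface_area(180.0, 80.0) == pytest.approx(2.0, abs=1e-12)
    assert index_to_bsa(284.0, 2.0) == pytest.approx(142.0)
    # formulas agree within 5% over the physiologic range (BMI 18.5-35)
    for h in np.linspace(150, 200, 6):
        for bmi in np.linspace(18.5, 35.0, 7):
            w = bmi * (h / 100.0) ** 2
            m = body_surface_area(h, w, "mosteller")
            d = body_surface_area(h, w, "dubois")
            assert abs(m - d) / m < 0.05
    with pytest.raises(DomainError):
        body_surface_area(-170.0, 70.0)


def test_full_volumetrics_pipeline(default_phantom):
    """ED = phantom contours, ES = same shape shrunk 20% about the center:
    areas scale by 0.8^2, so LVEF = 100 (1 - 0.64) = 36%."""
    stack, truth = default_phantom
    ed = truth.contours
    es = ContourSet()
    cx, cy = ed.lv_center
    for idx, sc in ed.slices.items():
        es.slices[idx] = SliceContours(
            endocardium=(sc.endocardium - [cx, cy]) * 0.8 + [cx, cy],
            epicardium=(sc.epicardium - [cx, cy]) * 0.8 + [cx, cy],
        )
    res = compute_volumetrics(ed, es, stack.slice_thickness_mm,
                              height_cm=180.0, weight_kg=80.0)
    assert res.LVEF_pct == pytest.approx(36.0, abs=1e-9)
    assert res.EDV_ml > res.ESV_ml > 0
    assert res.bsa_m2 == pytest.approx(2.0)
    assert res.EDVi_ml_per_m2 == pytest.approx(res.EDV_ml / 2.0)
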