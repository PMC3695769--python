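"""Chamber quantification: Simpson volumes, mass, area-length, dimensions."""

import math

import numpy as np
import pytest

from cmrpost import volumetry
from cmrpost.errors import ContourTopologyError, DomainError, MissingContourError
from cmrpost.geometry import (
    ContourStack,
    SliceGeometry,
    StudyMeta,
    regular_polygon,
)
from cmrpost.phantom import ellipsoid_ventricle_stack
from cmrpost.volumetry import (
    area_length_volume,
    classify_basal_slice,
    linear_dimensions,
    lv_assessment,
    lv_mass,
    rv_assessment,
    select_global_ed_es,
    slice_blood_volume,
    stroke_volume_consistency,
)


def _stack(area_endo=1000.0, thickness=8.0, gap=2.0, papillary_area=0.0, n_phases=1):
    # polygon with exact requested area: square of side sqrt(area)
    side = math.sqrt(area_endo)
    endo = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float) + 20.0
    contours = {}
    for p in range(n_phases):
        contours[(0, p, "endocardial")] = [
            volumetry.ContourPolygon(endo, role="endocardial")
        ]
        if papillary_area > 0:
            r = math.sqrt(papillary_area / math.pi)
            contours[(0, p, "papillary")] = [
                regular_polygon(20 + side / 2, 20 + side / 2, r, 512, "papillary")
            ]
    return ContourStack(
        [SliceGeometry(0, 0.0, thickness, gap)], contours, n_phases, StudyMeta()
    )


class TestSliceBloodVolume:
    def test_area_times_step(self):
        assert slice_blood_volume(_stack(), 0, 0, "included_in_blood") == pytest.approx(10.0)

    def test_papillary_modes(self):
        stack = _stack(papillary_area=100.0)
        blood = slice_blood_volume(stack, 0, 0, "included_in_blood")
        myo = slice_blood_volume(stack, 0, 0, "included_in_myocardium")
        assert blood == pytest.approx(10.0)
        assert myo == pytest.approx(9.0, rel=1e-3)

    def test_missing_contour(self):
        with pytest.raises(MissingContourError):
            slice_blood_volume(_stack(), 0, 1, "included_in_blood")


class TestEDESSelection:
    def test_argmax_argmin_and_tiebreak(self):
        # six phases with prescribed volumes via endo area
        volumes = [150.0, 130.0, 90.0, 60.0, 80.0, 120.0]
        contours = {}
        for p, v in enumerate(volumes):
            side = math.sqrt(v * 100.0)  # step 10 mm -> area = v*100 mm²
            sq = np.array([[0, 0], [side, 0], [side, side], [0, side]]) + 10.0
            contours[(0, p, "endocardial")] = [
                volumetry.ContourPolygon(sq, role="endocardial")
            ]
        stack = ContourStack([SliceGeometry(0, 0.0, 8.0, 2.0)], contours, 6, StudyMeta())
        assert select_global_ed_es(stack) == (0, 3)

        # tie for the minimum resolves to the earlier phase
        contours[(0, 5, "endocardial")] = contours[(0, 3, "endocardial")]
        stack2 = ContourStack([SliceGeometry(0, 0.0, 8.0, 2.0)], contours, 6, StudyMeta())
        assert select_global_ed_es(stack2)[1] == 3

    def test_phantom_extreme_phases(self):
        stack, truth = ellipsoid_ventricle_stack(n_phases=20)
        ed, es = select_global_ed_es(stack)
        assert (ed, es) == (truth.data["ed_phase"], truth.data["es_phase"])


class TestBasalSliceRules:
    def _two_phase_stack(self, ed_r, es_r, with_epi=True, epi_extra=10.0):
        contours = {}
        for p, r in enumerate((ed_r, es_r)):
            contours[(0, p, "endocardial")] = [
                regular_polygon(40, 40, r, 64, "endocardial")
            ]
            if with_epi:
                contours[(0, p, "epicardial")] = [
                    regular_polygon(40, 40, r + epi_extra, 64, "epicardial")
                ]
        # second slice so slice 0 is basal, not apical
        for p in range(2):
            contours[(1, p, "endocardial")] = [regular_polygon(40, 40, 14, 64, "endocardial")]
            contours[(1, p, "epicardial")] = [regular_polygon(40, 40, 22, 64, "epicardial")]
        return ContourStack(
            [SliceGeometry(0, 0.0, 8.0, 2.0), SliceGeometry(1, -10.0, 8.0, 2.0)],
            contours,
            2,
            StudyMeta(),
        )

    def test_ventricular_slice_kept(self):
        stack = self._two_phase_stack(20.0, 15.0)
        cls = classify_basal_slice(stack, 0, 0, 1)
        assert cls[0].classification == "ventricular_blood_and_mass"
        assert cls[1].classification == "ventricular_blood_and_mass"

    def test_atrium_excluded_when_expanding_without_myocardium(self):
        # no epicardium on slice 0 (adjacency 0) and cavity grows in systole
        stack = self._two_phase_stack(18.0, 21.0, with_epi=False)
        cls = classify_basal_slice(stack, 0, 0, 1)
        assert cls[1].classification == "atrium_exclude"

    def test_crescent_contributes_mass_only(self):
        contours = {
            (0, 0, "epicardial"): [regular_polygon(40, 40, 25, 64, "epicardial")],
            (1, 0, "endocardial"): [regular_polygon(40, 40, 15, 64, "endocardial")],
            (1, 0, "epicardial"): [regular_polygon(40, 40, 23, 64, "epicardial")],
            (2, 0, "endocardial"): [regular_polygon(40, 40, 12, 64, "endocardial")],
            (2, 0, "epicardial"): [regular_polygon(40, 40, 20, 64, "epicardial")],
        }
        stack = ContourStack(
            [SliceGeometry(k, -10.0 * k, 8.0, 2.0) for k in range(3)],
            contours,
            1,
            StudyMeta(),
        )
        cls = classify_basal_slice(stack, 0, 0, 0)
        assert cls[0].classification == "mass_only_crescent"
        # the crescent still adds wall to the mass computation
        assert lv_mass(stack, phase=0) > 0


class TestLVAssessment:
    def test_arithmetic_identities(self):
        stack, _ = ellipsoid_ventricle_stack(heart_rate=70.0, body_surface_area=2.0)
        res = lv_assessment(stack)
        assert res.sv == pytest.approx(res.edv - res.esv)
        assert res.ef == pytest.approx(100.0 * res.sv / res.edv)
        assert res.co == pytest.approx(res.sv * 70.0 / 1000.0)
        assert res.indexed["edv_ml_m2"] == pytest.approx(res.edv / 2.0)

    def test_sphere_simpson_within_2pct(self):
        stack, _ = ellipsoid_ventricle_stack((30, 30, 30), None, 5.0, 10.0, 0.0, 1)
        v = sum(
            slice_blood_volume(stack, s, 0, "included_in_blood")
            for s in stack.slices_with("endocardial", 0)
        )
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 27.0, rel=0.02)

    def test_refinement_reduces_error(self):
        truth = 4.0 / 3.0 * math.pi * 27.0
        errors = []
        for th in (10.0, 5.0, 2.5):
            stack, _ = ellipsoid_ventricle_stack((30, 30, 30), None, 5.0, th, 0.0, 1)
            v = sum(
                slice_blood_volume(stack, s, 0, "included_in_blood")
                for s in stack.slices_with("endocardial", 0)
            )
            errors.append(abs(v - truth))
        assert errors[0] > errors[1] > errors[2]

    def test_phantom_ef_recovered(self):
        stack, truth = ellipsoid_ventricle_stack(n_phases=20)
        res = lv_assessment(stack)
        assert res.ef == pytest.approx(truth.data["ef_pct"], abs=0.5)
        assert res.edv == pytest.approx(truth.data["edv_ml"], rel=0.02)

    def test_ef_invariant_under_scaling(self):
        stack, _ = ellipsoid_ventricle_stack(n_phases=8)
        scaled_contours = {
            key: [
                volumetry.ContourPolygon(p.vertices * 1.7, role=p.role) for p in polys
            ]
            for key, polys in stack.contours.items()
        }
        scaled = ContourStack(stack.slices, scaled_contours, stack.n_phases, stack.meta)
        assert lv_assessment(scaled).ef == pytest.approx(lv_assessment(stack).ef, rel=1e-6)


class TestLVMass:
    def test_density_constant(self):
        stack, _ = ellipsoid_ventricle_stack(n_phases=1, es_semi_axes=None)
        epi_ml = sum(
            volumetry.polygon_area(stack.get(s, 0, "epicardial"))
            * stack.geometry(s).step_mm
            for s in stack.slices_with("epicardial", 0)
        ) / 1000.0
        endo_ml = sum(
            volumetry.polygon_area(stack.get(s, 0, "endocardial"))
            * stack.geometry(s).step_mm
            for s in stack.slices_with("endocardial", 0)
        ) / 1000.0
        mass = lv_mass(stack)
        assert mass / (epi_ml - endo_ml) == pytest.approx(1.05, rel=1e-12)

    def test_zero_wall(self):
        endo = regular_polygon(40, 40, 20, 64, "endocardial")
        contours = {
            (0, 0, "endocardial"): [endo],
            (0, 0, "epicardial"): [
                volumetry.ContourPolygon(endo.vertices, role="epicardial")
            ],
        }
        stack = ContourStack([SliceGeometry(0, 0.0, 8.0, 2.0)], contours, 1, StudyMeta())
        assert lv_mass(stack) == pytest.approx(0.0, abs=1e-9)

    def test_papillary_tissue_conservation(self):
        """Moving papillaries between blood and myocardium conserves tissue."""
        stack, _ = ellipsoid_ventricle_stack(n_phases=1, es_semi_axes=None,
                                             papillary_area_mm2=150.0)
        vol_blood = sum(
            slice_blood_volume(stack, s, 0, "included_in_blood")
            for s in stack.slices_with("endocardial", 0)
        )
        vol_myo = sum(
            slice_blood_volume(stack, s, 0, "included_in_myocardium")
            for s in stack.slices_with("endocardial", 0)
        )
        d_mass = lv_mass(stack, "included_in_myocardium") - lv_mass(stack, "included_in_blood")
        assert d_mass == pytest.approx((vol_blood - vol_myo) * 1.05, rel=1e-9)

    def test_endo_outside_epi_rejected(self):
        contours = {
            (0, 0, "endocardial"): [regular_polygon(40, 40, 20, 64, "endocardial")],
            (0, 0, "epicardial"): [regular_polygon(40, 40, 25, 64, "epicardial")],
            (1, 0, "epicardial"): [regular_polygon(40, 40, 10, 64, "epicardial")],
            (1, 0, "endocardial"): [regular_polygon(90, 90, 18, 64, "endocardial")],
        }
        with pytest.raises(ContourTopologyError):
            ContourStack(
                [SliceGeometry(0, 0.0, 8.0, 2.0), SliceGeometry(1, -10.0, 8.0, 2.0)],
                contours,
                1,
                StudyMeta(),
            )


class TestAreaLength:
    def test_printed_equations(self):
        assert area_length_volume("single", 30.0, 8.0) == pytest.approx(95.625)
        assert area_length_volume("biplane", 30.0, 8.0, 20.0) == pytest.approx(63.75)

    def test_exact_ellipse_vs_spheroid(self):
        a, b = 4.0, 2.0  # cm
        v = area_length_volume("single", math.pi * a * b, 2 * a)
        v_spheroid = 4.0 / 3.0 * math.pi * a * b * b
        assert v / v_spheroid == pytest.approx(0.85 * 3 * math.pi / 8, rel=1e-12)
        assert v == pytest.approx(v_spheroid, rel=0.002)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            area_length_volume("single", -1.0, 8.0)
        with pytest.raises(DomainError):
            area_length_volume("biplane", 30.0, 8.0)


class TestRV:
    def test_same_math_path_as_lv(self):
        stack, _ = ellipsoid_ventricle_stack(n_phases=10)
        lv = lv_assessment(stack)
        rv = rv_assessment(stack)
        assert rv.edv == pytest.approx(lv.edv)
        assert rv.ef == pytest.approx(lv.ef)

    def test_mass_explicitly_not_computed(self):
        stack, _ = ellipsoid_ventricle_stack(n_phases=4)
        rv = rv_assessment(stack)
        assert rv.mass is None
        assert rv.mass_status == "not_computed"


class TestConsistency:
    @pytest.mark.parametrize(
        "lv, rv, consistent", [(80, 78, True), (80, 50, False), (80, 72, True)]
    )
    def test_flagging(self, lv, rv, consistent):
        rep = stroke_volume_consistency(lv, rv)
        assert rep.consistent is consistent
        assert rep.relative_difference == pytest.approx(abs(lv - rv) / lv)


class TestLinearDimensions:
    def test_concentric_annulus(self):
        endo = regular_polygon(0, 0, 25, 256, "endocardial")
        epi = regular_polygon(0, 0, 35, 256, "epicardial")
        cav, wp, wm = linear_dimensions(endo, epi, 123.0)
        assert cav == pytest.approx(50.0, rel=1e-3)
        assert wp == pytest.approx(10.0, rel=1e-2)
        assert wm == pytest.approx(10.0, rel=1e-2)

    def test_ellipse_major_axis(self):
        from cmrpost.geometry import ellipse_polygon

        endo = ellipse_polygon(0, 0, 30, 20, 256, "endocardial")
        epi = ellipse_polygon(0, 0, 40, 30, 256, "epicardial")
        cav, _, _ = linear_dimensions(endo, epi, 0.0)
        assert cav == pytest.approx(60.0, rel=1e-3)

    def test_matches_ray_casting_oracle(self):
        """Eccentric annulus agrees with a brute-force dense-boundary oracle."""
        endo = regular_polygon(3, 0, 20, 512, "endocardial")
        epi = regular_polygon(0, 0, 32, 512, "epicardial")
        cav, wp, wm = linear_dimensions(endo, epi, 0.0)
        # oracle: walk along the +x/-x axis from the endo centroid in fine steps
        import shapely

        c = endo.as_shapely().centroid
        e_poly, p_poly = endo.as_shapely(), epi.as_shapely()
        xs = np.linspace(0, 60, 60001)
        inside_e_pos = shapely.contains_xy(e_poly, c.x + xs, np.full_like(xs, c.y))
        inside_p_pos = shapely.contains_xy(p_poly, c.x + xs, np.full_like(xs, c.y))
        inside_e_neg = shapely.contains_xy(e_poly, c.x - xs, np.full_like(xs, c.y))
        inside_p_neg = shapely.contains_xy(p_poly, c.x - xs, np.full_like(xs, c.y))
        r_e_pos = xs[np.argmin(inside_e_pos)]
        r_e_neg = xs[np.argmin(inside_e_neg)]
        w_pos = xs[np.argmin(inside_p_pos)] - r_e_pos
        w_neg = xs[np.argmin(inside_p_neg)] - r_e_neg
        assert cav == pytest.approx(r_e_pos + r_e_neg, abs=0.01)
        assert wp == pytest.approx(w_pos, abs=0.01)
        assert wm == pytest.approx(w_neg, abs=0.01)
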