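"""Morphometry: heights, diameters, volumes, shape indices and angles."""

import math

import numpy as np
import pytest

from aneumorph import morphometry as mm
from aneumorph.synthetic import SacSpec, make_sac, transform_geometry
from aneumorph.types import Centerline, NeckAnnotation, ValidationError

from conftest import cone_geometry, random_rotation

HEMI_V = 2.0 * math.pi / 3.0
HEMI_S = 2.0 * math.pi


class TestHeights:
    def test_unit_hemisphere_heights_are_radius(self, hemisphere_geom):
        assert mm.height_max(hemisphere_geom) == pytest.approx(1.0, rel=1e-9)
        assert mm.height_perp(hemisphere_geom) == pytest.approx(1.0, rel=1e-9)

    def test_prolate_ellipsoid_perpendicular_height_is_semi_axis(self):
        geom = make_sac(SacSpec(a=2.597, b=2.597, c=4.032, refinement=4))
        assert mm.height_perp(geom) == pytest.approx(4.032, rel=1e-12)

    def test_tilted_sac_perpendicular_height_bounded_by_max_height(self, tilted_geom):
        assert mm.height_perp(tilted_geom) <= mm.height_max(tilted_geom) + 1e-12

    def test_generator_target_height_recovered(self, tilted_geom):
        truth = tilted_geom.metadata["truth"]
        assert mm.height_max(tilted_geom) == pytest.approx(truth["Hmax"], rel=1e-3)

    def test_rigid_motion_leaves_heights_unchanged(self, tilted_geom):
        rng = np.random.default_rng(4)
        moved = transform_geometry(tilted_geom, random_rotation(rng), rng.uniform(-30, 30, 3))
        assert mm.height_max(moved) == pytest.approx(mm.height_max(tilted_geom), abs=1e-9)
        assert mm.height_perp(moved) == pytest.approx(mm.height_perp(tilted_geom), abs=1e-9)


class TestDiameters:
    def test_hemisphere_middle_diameter_is_equator(self, hemisphere_geom):
        assert mm.diameter_middle(hemisphere_geom, n_slices=20) == pytest.approx(2.0, rel=1e-6)

    def test_oblate_half_ellipsoid_middle_diameter(self):
        geom = make_sac(SacSpec(a=3.0, b=3.0, c=1.0, refinement=4))
        assert mm.diameter_middle(geom, n_slices=50) == pytest.approx(6.0, rel=1e-3)

    def test_bumpy_sac_matches_dense_slicing_oracle(self):
        geom = make_sac(SacSpec(a=2.8, b=2.6, c=4.2, undulation_amplitude=0.5, refinement=4))
        coarse = mm.diameter_middle(geom, n_slices=100)
        dense = mm.diameter_middle(geom, n_slices=1000)
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_slice_count_validated(self, hemisphere_geom):
        with pytest.raises(ValidationError):
            mm.diameter_middle(hemisphere_geom, n_slices=1)

    def test_circular_neck_max_width(self):
        theta = 2 * math.pi * np.arange(64) / 64
        r = 3.2945
        neck = NeckAnnotation(
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 0.0, 1.0]),
            contour=np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(64)]),
        )
        assert mm.neck_diameter(neck) == pytest.approx(6.589, abs=1e-9)

    def test_unit_square_neck_closed_forms(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        neck = NeckAnnotation(
            plane_point=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0]), contour=square
        )
        assert mm.neck_diameter(neck, "max_width") == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert mm.neck_diameter(neck, "equivalent_area") == pytest.approx(
            2.0 / math.sqrt(math.pi), abs=1e-12
        )

    def test_elliptical_neck_max_width_is_major_axis(self):
        theta = 2 * math.pi * np.arange(64) / 64
        neck = NeckAnnotation(
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 0.0, 1.0]),
            contour=np.column_stack([2.5 * np.cos(theta), 1.5 * np.sin(theta), np.zeros(64)]),
        )
        assert mm.neck_diameter(neck) == pytest.approx(5.0, abs=1e-9)

    def test_too_few_contour_points_rejected(self):
        neck = NeckAnnotation(
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 0.0, 1.0]),
            contour=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        )
        with pytest.raises(ValidationError):
            mm.neck_diameter(neck)

    def test_constant_radius_vessel_diameter(self):
        s = np.linspace(-10, 10, 81)
        line = Centerline(
            points=np.column_stack([s, np.zeros_like(s), np.zeros_like(s)]),
            radii=np.full_like(s, 1.5125),
        )
        assert mm.vessel_diameter(line, np.array([0.0, 0.0, 1.5125])) == pytest.approx(
            3.025, abs=1e-12
        )

    def test_linear_radii_average_to_midpoint(self):
        s = np.linspace(-2.0, 2.0, 101)
        line = Centerline(
            points=np.column_stack([s, np.zeros_like(s), np.zeros_like(s)]),
            radii=np.interp(s, [-2.0, 2.0], [1.0, 2.0]),
        )
        # symmetric window around the closest point at s=0: mean radius 1.5
        assert mm.vessel_diameter(line, np.zeros(3), window_mm=2.0) == pytest.approx(3.0, abs=1e-9)

    def test_single_sample_window(self):
        line = Centerline(
            points=np.array([[0.0, 0, 0], [5.0, 0, 0]]), radii=np.array([1.2, 9.9])
        )
        assert mm.vessel_diameter(line, np.zeros(3), window_mm=0.1) == pytest.approx(2.4)


class TestVolumesAndHull:
    def test_hemisphere_closed_forms(self, hemisphere_geom):
        V, S = mm.sac_volume_area(hemisphere_geom)
        assert V == pytest.approx(HEMI_V, rel=5e-3)
        assert S == pytest.approx(HEMI_S, rel=5e-3)

    def test_refinement_converges_monotonically(self):
        errs_v, errs_s = [], []
        for level in (3, 4, 5):
            geom = make_sac(SacSpec(shape="hemisphere", radius=1.0, refinement=level))
            V, S = mm.sac_volume_area(geom)
            errs_v.append(abs(V - HEMI_V))
            errs_s.append(abs(S - HEMI_S))
        assert errs_v[0] > errs_v[1] > errs_v[2]
        assert errs_s[0] > errs_s[1] > errs_s[2]

    def test_hull_of_convex_sac_is_itself(self, hemisphere_geom):
        V, S = mm.sac_volume_area(hemisphere_geom)
        Vch, Sch = mm.hull_volume_area(hemisphere_geom)
        assert Vch == pytest.approx(V, rel=1e-6)
        assert Sch == pytest.approx(S, rel=1e-6)

    def test_indented_sac_hull_dominates(self):
        geom = make_sac(SacSpec(a=2.8, b=2.8, c=4.0, undulation_amplitude=0.6, refinement=4))
        V, _ = mm.sac_volume_area(geom)
        Vch, _ = mm.hull_volume_area(geom)
        assert Vch > V * 1.01


class TestShapeIndices:
    def test_undulation_index_printed_pair(self):
        # hull volume back-solved from the printed UI of an unruptured sac
        assert mm.undulation_index(140.293, 142.72) == pytest.approx(0.017, abs=5e-4)

    def test_undulation_index_zero_for_convex(self):
        assert mm.undulation_index(5.0, 5.0) == 0.0

    def test_undulation_index_monotone_in_volume(self):
        assert mm.undulation_index(2.0, 10.0) > mm.undulation_index(4.0, 10.0)

    def test_undulation_index_rejects_hull_violation(self):
        with pytest.raises(ValidationError):
            mm.undulation_index(11.0, 10.0)

    def test_ellipticity_index_zero_for_hemisphere_closed_form(self):
        assert mm.ellipticity_index(HEMI_V, HEMI_S) == pytest.approx(0.0, abs=1e-9)

    def test_ellipticity_index_grows_with_elongation(self):
        values = []
        for c_over_a in (1.0, 2.0, 4.0):
            a = (3.0 / (2.0 * math.pi * c_over_a)) ** (1.0 / 3.0)  # fixed hull volume
            geom = make_sac(SacSpec(a=a, b=a, c=a * c_over_a, refinement=4))
            Vch, Sch = mm.hull_volume_area(geom)
            values.append(mm.ellipticity_index(Vch, Sch))
        assert values[0] < values[1] < values[2]

    def test_ellipticity_index_limit_is_one(self):
        assert mm.ellipticity_index(1.0, 1e12) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "V,S,expected",
        [
            (333.099, 206.884, 0.108),
            (27.768, 35.333, 0.004),
            (48.090, 58.129, 0.127),
        ],
    )
    def test_nonsphericity_index_reproduces_printed_values(self, V, S, expected):
        assert round(mm.nonsphericity_index(V, S), 3) == expected

    def test_nonsphericity_index_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            mm.nonsphericity_index(-1.0, 2.0)

    def test_indices_invariant_under_rigid_motion_and_scaling(self, tilted_geom):
        rng = np.random.default_rng(9)
        base = mm.compute_all(tilted_geom, n_slices=20)
        moved = transform_geometry(tilted_geom, random_rotation(rng), rng.uniform(-20, 20, 3))
        res = mm.compute_all(moved, n_slices=20)
        for name in ("UI", "EI", "NSI", "AR", "SR", "Hmax", "H", "Dneck", "Dvessel"):
            assert getattr(res, name) == pytest.approx(getattr(base, name), abs=1e-6)
        # uniform scaling: indices and ratios fixed, lengths linear, V cubic
        k = 2.5
        scaled = transform_geometry(tilted_geom, np.eye(3), np.zeros(3))
        scaled.sac.vertices *= k
        scaled.neck.plane_point *= k
        scaled.neck.contour *= k
        scaled.parent.points *= k
        scaled.parent.radii *= k
        res_k = mm.compute_all(scaled, n_slices=20)
        for name in ("UI", "EI", "NSI", "AR", "SR"):
            assert getattr(res_k, name) == pytest.approx(getattr(base, name), abs=1e-9)
        assert res_k.Hmax == pytest.approx(k * base.Hmax, rel=1e-12)
        assert res_k.V == pytest.approx(k**3 * base.V, rel=1e-12)


class TestAngles:
    def test_perpendicular_sac_gives_90(self):
        geom = cone_geometry(apex=[0.0, 0.0, 3.0])
        assert mm.vessel_angle(geom) == pytest.approx(90.0, abs=1e-9)
        assert mm.inclination_angle(geom) == pytest.approx(90.0, abs=1e-9)

    def test_downstream_tilt_exceeds_90(self):
        # axis tilted 30 degrees downstream from perpendicular
        geom = cone_geometry(apex=[3.0 * math.sin(math.radians(30)), 0.0, 3.0 * math.cos(math.radians(30))])
        assert mm.vessel_angle(geom) == pytest.approx(120.0, abs=1e-9)
        assert mm.inclination_angle(geom) == pytest.approx(120.0, abs=1e-9)

    def test_in_plane_axis_extremes(self):
        # apex just above the plane pointing proximally / distally
        prox = cone_geometry(apex=[-3.0, 0.0, 1e-4])
        dist = cone_geometry(apex=[3.0, 0.0, 1e-4])
        assert mm.inclination_angle(prox) == pytest.approx(0.0, abs=0.01)
        assert mm.inclination_angle(dist) == pytest.approx(180.0, abs=0.01)

    def test_generator_angles_recovered_within_one_degree(self, tilted_geom):
        truth = tilted_geom.metadata["truth"]
        assert mm.vessel_angle(tilted_geom) == pytest.approx(truth["thetaF"], abs=1.0)
        assert mm.inclination_angle(tilted_geom) == pytest.approx(truth["thetaA"], abs=1.0)


class TestRatiosAndPanel:
    @pytest.mark.parametrize(
        "func,num,den,expected",
        [
            (mm.aspect_ratio, 5.138, 6.589, 0.780),
            (mm.aspect_ratio, 6.865, 7.446, 0.922),
            (mm.size_ratio, 5.311, 3.760, 1.413),
            (mm.size_ratio, 7.578, 3.025, 2.505),
        ],
    )
    def test_printed_ratios(self, func, num, den, expected):
        assert round(func(num, den), 3) == expected

    def test_ratio_of_equal_arguments_is_one(self):
        assert mm.aspect_ratio(3.3, 3.3) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            mm.size_ratio(5.0, 0.0)

    def test_panel_algebraic_identity(self, tilted_geom):
        r = mm.compute_all(tilted_geom, n_slices=20)
        assert r.AR == pytest.approx(r.SR * (r.Dvessel / r.Dneck) * (r.H / r.Hmax), rel=1e-12)

    def test_panel_without_centerline_has_null_vessel_entries(self, tilted_geom):
        from aneumorph.types import AneurysmGeometry

        geom = AneurysmGeometry(sac=tilted_geom.sac, neck=tilted_geom.neck, parent=None)
        r = mm.compute_all(geom, n_slices=20)
        assert r.Dvessel is None and r.SR is None
        assert r.thetaF is None and r.thetaA is None
        assert r.V > 0 and r.NSI is not None
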