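"""WSS postprocessing: cycle selection, TAWSS/OSI/RRT and sac averages."""

import math

import numpy as np
import pytest

from aneumorph import hemodynamics as hd
from aneumorph.synthetic import FlowSpec, SacSpec, make_sac, make_wss_series
from aneumorph.types import TriSurface, ValidationError, WSSField

from conftest import flat_patch


def uniform_field(surface, times, vector_of_t):
    """WSSField with the same vector at every vertex, varying over time."""
    nv = len(surface.vertices)
    vecs = np.stack([np.tile(np.asarray(v, dtype=float), (nv, 1)) for v in vector_of_t])
    return WSSField(surface=surface, times=np.asarray(times, dtype=float), vectors=vecs)


@pytest.fixture(scope="module")
def patch():
    return flat_patch(n=8, extent=2.0)


class TestSelectCycle:
    def test_third_cycle_is_rezeroed(self, patch):
        spec = FlowSpec(period=1.0, samples_per_cycle=40, n_cycles=3, mean_pa=1.0, osc_pa=0.5)
        series = make_wss_series(patch, spec)
        cyc = hd.select_cycle(series, period=1.0, cycle_index=3)
        assert cyc.times[0] == pytest.approx(0.0, abs=1e-12)
        assert cyc.times[-1] == pytest.approx(1.0, abs=1e-12)

    def test_periodic_cycles_are_identical(self, patch):
        spec = FlowSpec(period=1.0, samples_per_cycle=40, n_cycles=3, mean_pa=1.0, osc_pa=0.5)
        series = make_wss_series(patch, spec)
        c2 = hd.select_cycle(series, 1.0, 2)
        c3 = hd.select_cycle(series, 1.0, 3)
        assert np.allclose(c2.times, c3.times, atol=1e-12)
        assert np.allclose(c2.vectors, c3.vectors, atol=1e-12)

    def test_cycle_beyond_span_rejected(self, patch):
        spec = FlowSpec(period=1.0, samples_per_cycle=40, n_cycles=3)
        series = make_wss_series(patch, spec)
        with pytest.raises(ValidationError):
            hd.select_cycle(series, 1.0, 4)


class TestTawss:
    def test_constant_magnitude(self, patch):
        f = uniform_field(patch, [0.0, 0.5, 1.0], [[1, 0, 0]] * 3)
        assert hd.tawss(f) == pytest.approx(1.0)

    def test_rectified_sinusoid_closed_form(self, patch):
        t = np.linspace(0.0, 1.0, 201)
        f = uniform_field(patch, t, [[math.sin(2 * math.pi * ti), 0.0, 0.0] for ti in t])
        assert hd.tawss(f) == pytest.approx(2.0 / math.pi, rel=5e-3)

    def test_generator_closed_form(self, patch):
        f = make_wss_series(patch, FlowSpec(mean_pa=0.7, osc_pa=1.3, samples_per_cycle=200))
        assert hd.tawss(f) == pytest.approx(f.metadata["tawss"], rel=1e-3)

    def test_single_sample_rejected(self, patch):
        f = uniform_field(patch, [0.0], [[1, 0, 0]])
        with pytest.raises(ValidationError):
            hd.tawss(f)

    def test_quadrature_error_scales_quadratically(self, patch):
        # partial-span average of a smooth |tau| (a full periodic cycle would
        # converge spectrally and hide the O(dt^2) trapezoid order)
        def field(n):
            t = np.linspace(0.0, 0.4, n + 1)
            w = 2 * math.pi * t
            vecs = [[(1 + 0.5 * math.sin(wi)), 0.3 * math.cos(wi), 0.0] for wi in w]
            return uniform_field(patch, t, vecs)

        ref = hd.tawss(field(6400))[0]
        errs = [abs(hd.tawss(field(n))[0] - ref) for n in (50, 100, 200)]
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.3)


class TestOsi:
    def test_unidirectional_constant_is_zero(self, patch):
        f = uniform_field(patch, [0.0, 0.5, 1.0], [[2, 0, 0]] * 3)
        assert hd.osi(f) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_sinusoid_is_half(self, patch):
        t = np.linspace(0.0, 1.0, 201)
        f = uniform_field(patch, t, [[math.sin(2 * math.pi * ti), 0.0, 0.0] for ti in t])
        assert hd.osi(f) == pytest.approx(0.5, abs=1e-9)

    def test_non_reversing_pulsatile_is_zero(self, patch):
        f = make_wss_series(patch, FlowSpec(mean_pa=1.0, osc_pa=0.6, samples_per_cycle=100))
        assert hd.osi(f) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_vertex_warns_and_is_zero(self, patch):
        f = uniform_field(patch, [0.0, 0.5, 1.0], [[0, 0, 0]] * 3)
        with pytest.warns(UserWarning, match="zero WSS"):
            assert hd.osi(f) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fields_stay_in_range(self, patch, seed):
        rng = np.random.default_rng(seed)
        nt, nv = 24, len(patch.vertices)
        f = WSSField(
            surface=patch,
            times=np.sort(rng.uniform(0.0, 1.0, nt - 2).tolist() + [0.0, 1.0]),
            vectors=rng.standard_normal((nt, nv, 3)) * rng.uniform(0.1, 5.0),
        )
        o = hd.osi(f)
        assert np.all(o >= 0.0) and np.all(o <= 0.5)


class TestRrt:
    def test_constant_two_pascal(self, patch):
        f = uniform_field(patch, [0.0, 1.0], [[2, 0, 0]] * 2)
        assert hd.rrt(f) == pytest.approx(0.5)

    def test_formula_value(self):
        # RRT = 1 / ((1 - 2 OSI) TAWSS): OSI = 0.25, TAWSS = 1 -> 2
        assert 1.0 / ((1.0 - 2.0 * 0.25) * 1.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_reciprocal_mean_vector_identity(self, patch, seed):
        rng = np.random.default_rng(100 + seed)
        nt, nv = 30, len(patch.vertices)
        times = np.linspace(0.0, 1.0, nt)
        f = WSSField(surface=patch, times=times, vectors=rng.standard_normal((nt, nv, 3)) + 0.5)
        mean_vec = np.trapezoid(f.vectors, times, axis=0) / (times[-1] - times[0])
        expected = 1.0 / np.linalg.norm(mean_vec, axis=1)
        assert np.allclose(hd.rrt(f), expected, rtol=1e-9)

    def test_fully_oscillatory_vertex_capped(self, patch):
        t = np.linspace(0.0, 1.0, 101)
        f = uniform_field(patch, t, [[math.sin(2 * math.pi * ti), 0.0, 0.0] for ti in t])
        with pytest.warns(UserWarning, match="capped"):
            assert np.all(hd.rrt(f) == hd.RRT_CAP)

    @pytest.mark.parametrize("seed", range(5))
    def test_pointwise_product_identity(self, patch, seed):
        rng = np.random.default_rng(seed)
        nt, nv = 20, len(patch.vertices)
        f = WSSField(
            surface=patch,
            times=np.linspace(0.0, 0.8, nt),
            vectors=rng.standard_normal((nt, nv, 3)) + 1.0,
        )
        prod = hd.rrt(f) * (1.0 - 2.0 * hd.osi(f)) * hd.tawss(f)
        assert np.allclose(prod, 1.0, atol=1e-9)


class TestSacAverage:
    def test_constant_map(self, patch):
        assert hd.sac_average(np.full(len(patch.vertices), 3.7), patch) == pytest.approx(3.7)

    def test_linear_field_equals_centroid_value(self, patch):
        # area-weighted barycentric vertex mean integrates linear fields exactly
        g = 2.0 * patch.vertices[:, 0] - 0.5 * patch.vertices[:, 1] + 1.0
        centroid_val = 2.0 * 1.0 - 0.5 * 1.0 + 1.0  # patch centroid at (1, 1)
        assert hd.sac_average(g, patch) == pytest.approx(centroid_val, abs=1e-9)

    def test_refinement_stability(self):
        def value(n):
            p = flat_patch(n=n, extent=2.0)
            g = np.sin(p.vertices[:, 0]) * np.cos(p.vertices[:, 1])
            return hd.sac_average(g, p)

        assert value(120) == pytest.approx(value(60), rel=1e-3)

    def test_size_mismatch_rejected(self, patch):
        with pytest.raises(ValidationError):
            hd.sac_average(np.ones(3), patch)


class TestNwss:
    def test_identical_fields(self, patch):
        f = make_wss_series(patch, FlowSpec(mean_pa=1.2, osc_pa=0.4))
        assert hd.nwss(f, f) == pytest.approx(1.0)

    def test_half_magnitude(self, patch):
        sac = make_wss_series(patch, FlowSpec(mean_pa=0.6))
        parent = make_wss_series(patch, FlowSpec(mean_pa=1.2))
        assert hd.nwss(sac, parent) == pytest.approx(0.5, rel=1e-9)

    def test_constructed_ratio(self, patch):
        # sac/parent mean ratio built to the 0.487 normalized-WSS level
        sac = make_wss_series(patch, FlowSpec(mean_pa=0.487))
        parent = make_wss_series(patch, FlowSpec(mean_pa=1.0))
        assert hd.nwss(sac, parent) == pytest.approx(0.487, rel=1e-3)

    def test_zero_parent_rejected(self, patch):
        sac = make_wss_series(patch, FlowSpec(mean_pa=1.0))
        parent = make_wss_series(patch, FlowSpec(mean_pa=0.0, osc_pa=0.0))
        with pytest.raises(ValidationError):
            hd.nwss(sac, parent)

    def test_common_scaling_invariance(self, patch):
        sac = make_wss_series(patch, FlowSpec(mean_pa=0.8, osc_pa=0.2))
        parent = make_wss_series(patch, FlowSpec(mean_pa=1.6, osc_pa=0.4))
        base = hd.nwss(sac, parent)
        sac.vectors *= 3.0
        parent.vectors *= 3.0
        assert hd.nwss(sac, parent) == pytest.approx(base, rel=1e-12)


class TestSummary:
    def test_full_panel_on_synthetic_sac(self):
        geom = make_sac(SacSpec(a=2.6, b=2.6, c=4.0, refinement=3))
        sac_field = make_wss_series(geom.sac, FlowSpec(mean_pa=0.5, osc_pa=1.0))
        parent_field = make_wss_series(geom.sac, FlowSpec(mean_pa=1.0))
        res = hd.compute_summary(sac_field, parent_field)
        cf_tawss = sac_field.metadata["tawss"][0]
        cf_osi = sac_field.metadata["osi"][0]
        assert res.OSI == pytest.approx(cf_osi, rel=1e-3)
        assert res.NWSS == pytest.approx(cf_tawss / 1.0, rel=1e-3)
        assert np.all(res.rrt_map >= 1.0 / res.tawss_map - 1e-12)

    def test_rotation_invariance_of_tawss(self, patch):
        rng = np.random.default_rng(2)
        f = make_wss_series(patch, FlowSpec(mean_pa=1.0, osc_pa=0.5))
        base = hd.tawss(f).copy()
        from conftest import random_rotation

        R = random_rotation(rng)
        f.vectors = f.vectors @ R.T
        assert np.allclose(hd.tawss(f), base, rtol=1e-12)
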