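"""Forward model: osmotic responses, geometry evolution, rendering."""

import math

import numpy as np
import pytest

from octeye import (GeometryError, ScheduleError, TruncationError,
                    eye_at_time, mouse_geometry, osmotic_response,
                    render_bscan, render_timeseries)
from octeye.phantom import (ArcSurface, EyeGeometry, ImagingConfig,
                            TissueOptics, trace_column)
from octeye.scenario import OsmoticScenario, Phase, PhaseResponse


def _scenario(amplitude=-0.207, tau=3.0, param="CCT"):
    return OsmoticScenario(name="t", phases=[
        Phase(osmolality=250, duration_min=10, frames_per_min=0.2),
        Phase(osmolality=1000, duration_min=20, frames_per_min=1,
              responses={param: PhaseResponse(amplitude=amplitude, tau_min=tau)}),
        Phase(osmolality=250, duration_min=60, frames_per_min=0.2),
    ])


class TestOsmoticResponse:
    def test_zero_amplitude_is_constant(self):
        sc = _scenario(amplitude=0.0)
        for t in (-3, 0, 5, 15, 40):
            assert osmotic_response(119.0, sc, t, "CCT") == pytest.approx(119.0)

    def test_closed_form_at_three_time_constants(self):
        # normalized change after 3 tau: amplitude * (1 - e^-3)
        sc = _scenario(amplitude=-0.207, tau=3.0)
        v = osmotic_response(119.0, sc, 10.0 + 9.0, "CCT")
        change = 100.0 * (v - 119.0) / 119.0
        assert change == pytest.approx(-20.7 * (1 - math.exp(-3)), abs=1e-9)
        assert change == pytest.approx(-19.6694, abs=1e-3)

    def test_reversal_relaxes_back_to_baseline(self):
        sc = _scenario(amplitude=-0.207, tau=1.0)
        late = osmotic_response(119.0, sc, 90.0, "CCT")
        assert late == pytest.approx(119.0, rel=1e-4)

    def test_tiny_tau_reaches_asymptote_within_one_frame(self):
        sc = _scenario(amplitude=-0.2, tau=1e-4)
        v = osmotic_response(100.0, sc, 11.0, "CCT")
        assert v == pytest.approx(80.0, rel=1e-6)

    def test_continuity_across_phase_boundary(self):
        sc = _scenario(amplitude=-0.15, tau=2.0)
        for t_edge in (10.0, 30.0):
            lo = osmotic_response(119.0, sc, t_edge - 1e-6, "CCT")
            hi = osmotic_response(119.0, sc, t_edge + 1e-6, "CCT")
            assert lo == pytest.approx(hi, abs=1e-3)

    def test_out_of_schedule_raises(self):
        sc = _scenario()
        with pytest.raises(ScheduleError):
            osmotic_response(119.0, sc, 1000.0, "CCT")
        with pytest.raises(ScheduleError):
            osmotic_response(119.0, sc, -50.0, "CCT")


class TestEyeAtTime:
    def test_identity_at_time_zero(self, mouse_geom, optics):
        sc = _scenario()
        g, o = eye_at_time(sc, mouse_geom, optics, 0.0)
        assert g.cct == pytest.approx(mouse_geom.cct)
        assert g.acd == pytest.approx(mouse_geom.acd)
        assert g.lt == pytest.approx(mouse_geom.lt)
        assert g.crd == pytest.approx(mouse_geom.crd)
        assert g.iris_sag == pytest.approx(mouse_geom.iris_sag)
        assert o.lens_multiplier == pytest.approx(1.0)

    def test_hypertonic_signs(self, mouse_geom, optics):
        from octeye import load_scenario
        sc = load_scenario("group1")
        g, o = eye_at_time(sc, mouse_geom, optics, 23.0)
        assert g.cct < mouse_geom.cct
        assert g.acd < mouse_geom.acd
        assert g.lt == pytest.approx(mouse_geom.lt, rel=1e-6)  # LT unchanged
        assert g.iris_sag > mouse_geom.iris_sag                # convex iris
        assert o.lens_multiplier > 1.0                         # opacification

    def test_hypotonic_iris_concave(self, mouse_geom, optics):
        from octeye import load_scenario
        sc = load_scenario("group3")
        g, _ = eye_at_time(sc, mouse_geom, optics, 34.0)
        assert g.iris_sag < 0

    def test_impossible_amplitude_rejected(self, mouse_geom, optics):
        sc = _scenario(amplitude=-2.5, tau=0.5, param="ACD")
        with pytest.raises(GeometryError):
            eye_at_time(sc, mouse_geom, optics, 25.0)


def _flat_eye():
    """All-flat interfaces for the normal-incidence additivity check."""
    return EyeGeometry(
        cornea_anterior=ArcSurface(150.0, math.inf, 900.0),
        cornea_posterior=ArcSurface(269.0, math.inf, 900.0),
        lens_anterior=ArcSurface(673.0, math.inf, 900.0),
        lens_posterior=ArcSurface(2533.0, math.inf, 900.0),
        ilm=ArcSurface(3349.0, math.inf, 2000.0),
        iris=None, lateral_extent=950.0,
    ).validate()


class TestRendering:
    def test_optical_path_additivity_flat_normal_incidence(self, optics):
        geom = _flat_eye()
        tr = trace_column(geom, optics, 0.0)
        # optical depth of each interface = cumulative sum of n_i * t_i
        expected = {
            "cornea_anterior": 150.0,
            "cornea_posterior": 150.0 + 119.0 * 1.40,
            "lens_anterior": 150.0 + 119.0 * 1.40 + 404.0 * 1.33,
            "lens_posterior": 150.0 + 119.0 * 1.40 + 404.0 * 1.33 + 1860.0 * 1.57,
            "ilm": 150.0 + 119.0 * 1.40 + 404.0 * 1.33 + 1860.0 * 1.57
                   + 816.0 * 1.33,
        }
        for label, opl in expected.items():
            assert tr.crossings[label][0] == pytest.approx(opl, abs=1e-9)
        # and the rendered image carries those boundaries at opl / pitch
        img = render_bscan(geom, optics)
        col = img.data[:, img.data.shape[1] // 2]
        row = expected["cornea_anterior"] / img.axial_pitch
        assert col[int(row) - 2] < 0.1 and col[int(row) + 2] > 0.3

    def test_corneal_optical_thickness_on_axis(self, mouse_geom, optics):
        tr = trace_column(mouse_geom, optics, 0.0)
        opt_cct = tr.crossings["cornea_posterior"][0] - tr.crossings["cornea_anterior"][0]
        assert opt_cct == pytest.approx(119.0 * 1.40, abs=1e-6)  # 166.6 μm

    def test_noiseless_render_is_deterministic(self, mouse_geom, optics):
        a = render_bscan(mouse_geom, optics)
        b = render_bscan(mouse_geom, optics)
        assert np.array_equal(a.data, b.data)

    def test_seeded_noise_is_reproducible_and_seed_dependent(self, mouse_geom, optics):
        a = render_bscan(mouse_geom, optics, noise_seed=5)
        b = render_bscan(mouse_geom, optics, noise_seed=5)
        c = render_bscan(mouse_geom, optics, noise_seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_shallow_image_raises_truncation(self, mouse_geom, optics):
        shallow = ImagingConfig(axial_pitch=3.0, lateral_pitch=10.0,
                                n_rows=800, n_cols=64)
        with pytest.raises(TruncationError):
            render_bscan(mouse_geom, optics, shallow)

    def test_negative_intensities_never_rendered(self, mouse_geom, optics):
        img = render_bscan(mouse_geom, optics, noise_seed=1)
        assert np.all(img.data >= 0)


class TestTimeseries:
    def test_control_frame_count_and_truth(self):
        from octeye import load_scenario
        sc = load_scenario("control")
        frames, truth = render_timeseries(sc, seed=0)
        assert len(frames) == 17
        assert len(truth) == 17
        base = truth[truth.t_min <= 0]
        assert np.allclose(base.CCT, 119.0)
        assert np.allclose(base.CRD, 3080.0)

    def test_fixed_seed_stack_is_bitwise_identical(self):
        from octeye import load_scenario
        sc = load_scenario("model_eye")
        a, _ = render_timeseries(sc, seed=4, noise=True)
        b, _ = render_timeseries(sc, seed=4, noise=True)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))


def test_mouse_geometry_matches_in_vivo_baselines(mouse_geom):
    assert mouse_geom.cct == pytest.approx(119.0)
    assert mouse_geom.acd == pytest.approx(404.0)
    assert mouse_geom.lt == pytest.approx(1860.0)
    assert mouse_geom.crd == pytest.approx(3080.0)
    assert mouse_geom.crd > mouse_geom.acd + mouse_geom.lt


def test_geometry_ordering_enforced():
    geom = _flat_eye()
    bad = EyeGeometry(
        cornea_anterior=geom.cornea_anterior,
        cornea_posterior=ArcSurface(100.0, math.inf, 900.0),  # above anterior
        lens_anterior=geom.lens_anterior,
        lens_posterior=geom.lens_posterior,
        ilm=geom.ilm, iris=None)
    with pytest.raises(GeometryError):
        bad.validate()


def test_tissue_optics_validation():
    with pytest.raises(GeometryError):
        TissueOptics(n_cornea=0.9)
    with pytest.raises(GeometryError):
        TissueOptics(lens_front_fraction=1.5)
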