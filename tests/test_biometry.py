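"""The six parameters: axial distances, lens scattering, iris curvature."""

import math

import numpy as np
import pytest

from octeye import MeasurementError, measure_ic, measure_lsi
from octeye.biometry import BiometryRecord, _chord_deviation, measure_axial
from octeye.phantom import BScanImage
from octeye.refraction import ArcModel, CorrectedSurfaceSet


class TestAxial:
    def test_model_eye_matches_manufacturer_dimensions(self, model_eye_analysis):
        rec, _, _ = model_eye_analysis
        pitch = 6.0  # model-eye axial pixel (μm of optical path)
        assert rec.CCT == pytest.approx(550.0, abs=2 * pitch)
        assert rec.ACD == pytest.approx(3030.0, abs=3 * pitch)
        assert rec.LT == pytest.approx(3900.0, abs=4 * pitch)

    def test_mouse_baseline_recovery(self, baseline_analysis):
        rec, _, _ = baseline_analysis
        assert rec.CCT == pytest.approx(119.0, abs=6.0)
        assert rec.ACD == pytest.approx(404.0, abs=9.0)
        assert rec.LT == pytest.approx(1860.0, abs=12.0)
        assert rec.CRD == pytest.approx(3080.0, abs=15.0)

    def test_vitreous_depth_is_positive(self, baseline_analysis):
        rec, _, _ = baseline_analysis
        assert rec.CRD > rec.ACD + rec.LT

    def test_degenerate_layer_is_an_error(self):
        flat = lambda z: ArcModel(cx=0.0, cz=z, radius=math.inf, z0=z)
        pts = lambda z: np.column_stack([np.linspace(-100, 100, 5), np.full(5, z)])
        surfaces = CorrectedSurfaceSet(
            traces={"cornea_anterior": pts(100.0), "cornea_posterior": pts(100.0)},
            arcs={"cornea_anterior": flat(100.0), "cornea_posterior": flat(100.0)},
            indices={})
        with pytest.raises(MeasurementError):
            measure_axial(surfaces)

    def test_record_validation_enforces_crd_bound(self):
        rec = BiometryRecord(CCT=119, ACD=400, LT=1800, CRD=2000, LSI=0.3, IC=0)
        with pytest.raises(MeasurementError):
            rec.validate()

    def test_missing_surface_fails_only_its_parameters(self):
        flat = lambda z: ArcModel(cx=0.0, cz=z, radius=math.inf, z0=z)
        pts = lambda z: np.column_stack([np.linspace(-100, 100, 5), np.full(5, z)])
        surfaces = CorrectedSurfaceSet(
            traces={"cornea_anterior": pts(100.0), "cornea_posterior": pts(220.0)},
            arcs={"cornea_anterior": flat(100.0), "cornea_posterior": flat(220.0)},
            indices={})
        out = measure_axial(surfaces)
        assert out["CCT"] == pytest.approx(120.0)
        assert math.isnan(out["ACD"]) and math.isnan(out["CRD"])


class TestLSI:
    def test_uniform_lens_gives_layer_intensity(self, baseline_image,
                                                baseline_analysis):
        _, raw, _ = baseline_analysis
        lsi = measure_lsi(baseline_image, raw)
        assert lsi == pytest.approx(0.35, rel=1e-3)

    def test_region_fraction_irrelevant_for_uniform_lens(self, baseline_image,
                                                         baseline_analysis):
        _, raw, _ = baseline_analysis
        a = measure_lsi(baseline_image, raw, region_fraction=0.10)
        b = measure_lsi(baseline_image, raw, region_fraction=0.25)
        assert a == pytest.approx(b, rel=1e-3)

    def test_linearity_under_intensity_rescale(self, baseline_image,
                                               baseline_analysis):
        _, raw, _ = baseline_analysis
        doubled = BScanImage(baseline_image.data * 2.0,
                             baseline_image.axial_pitch,
                             baseline_image.lateral_pitch)
        assert measure_lsi(doubled, raw) == pytest.approx(
            2.0 * measure_lsi(baseline_image, raw), rel=1e-9)

    def test_group1_peak_opacification_ratio(self, group1_run):
        """At the end of the hypertonic phase the anterior-lens backscatter
        has risen by ~28.8 % over baseline."""
        _, _, _, measured = group1_run
        baseline = measured.head(5)["LSI"].mean()
        peak = measured.loc[measured.t_min == 23.0, "LSI"].iloc[0]
        assert peak / baseline == pytest.approx(1.288, abs=0.02)

    def test_invalid_region_fraction(self, baseline_image, baseline_analysis):
        _, raw, _ = baseline_analysis
        with pytest.raises(MeasurementError):
            measure_lsi(baseline_image, raw, region_fraction=0.0)


def _wing_set(z_of_x, x_lo=200.0, x_hi=800.0, n=61):
    x = np.linspace(x_lo, x_hi, n)
    pts = np.column_stack([x, z_of_x(x)])
    return CorrectedSurfaceSet(traces={"iris_ipe_right": pts}, arcs={},
                               indices={}, axis_x=0.0)


class TestIC:
    def test_flat_iris_is_zero(self):
        surfaces = _wing_set(lambda x: np.full_like(x, 700.0))
        ic, flags = measure_ic(surfaces)
        assert ic == pytest.approx(0.0, abs=1e-6)
        assert flags  # no lens available -> tip fallback is flagged

    def test_semicircle_chord_deviation_equals_radius(self):
        """Geometry oracle: a semicircular arc over its diameter chord has
        maximum perpendicular distance exactly R."""
        R = 300.0
        x = np.linspace(-R, R, 401)
        z = 900.0 - np.sqrt(R * R - x * x)
        ic = _chord_deviation(x, z, np.array([-R, 900.0]), np.array([R, 900.0]))
        assert ic == pytest.approx(R, rel=1e-3)

    def test_parabolic_wing_recovers_sag(self):
        sag = 40.0
        surfaces = _wing_set(
            lambda x: 700.0 - 4 * sag * ((x - 200) / 600) * (1 - (x - 200) / 600))
        ic, _ = measure_ic(surfaces)
        assert ic == pytest.approx(sag, rel=0.02)

    def test_antisymmetry_under_mirroring(self):
        """Mirroring the wing about its chord flips the IC sign."""
        sag = 35.0
        bow = lambda x: 700.0 - 4 * sag * ((x - 200) / 600) * (1 - (x - 200) / 600)
        up, _ = measure_ic(_wing_set(bow))
        down, _ = measure_ic(_wing_set(lambda x: 1400.0 - bow(x)))
        assert down == pytest.approx(-up, rel=1e-6)

    def test_group4_signs_follow_tonicity(self, group4_run):
        _, _, _, measured = group4_run
        iso = measured.loc[measured.t_min == 10.0, "IC"].iloc[0]
        hyper = measured.loc[measured.t_min == 30.0, "IC"].iloc[0]
        hypo = measured.loc[measured.t_min == 50.0, "IC"].iloc[0]
        assert hyper > iso > 0 > hypo   # convex under dehydration, concave under hydration

    def test_no_iris_is_an_error(self):
        empty = CorrectedSurfaceSet(traces={}, arcs={}, indices={})
        with pytest.raises(MeasurementError):
            measure_ic(empty)


class TestInvariances:
    def test_axial_parameters_invariant_to_decentring(self, baseline_analysis,
                                                      optics):
        from octeye import analyze_bscan, mouse_geometry, render_bscan
        rec0, _, _ = baseline_analysis
        rec1, _, _ = analyze_bscan(
            render_bscan(mouse_geometry(axis_x=200.0), optics), optics=optics)
        for p in ("CCT", "ACD", "LT", "CRD"):
            assert getattr(rec1, p) == pytest.approx(getattr(rec0, p), abs=6.0)

    def test_axial_parameters_invariant_to_intensity_scale(self, baseline_image,
                                                           baseline_analysis,
                                                           optics):
        from octeye import analyze_bscan
        rec0, _, _ = baseline_analysis
        scaled = BScanImage(baseline_image.data * 3.0, baseline_image.axial_pitch,
                            baseline_image.lateral_pitch)
        rec1, _, _ = analyze_bscan(scaled, optics=optics)
        for p in ("CCT", "ACD", "LT", "CRD"):
            assert getattr(rec1, p) == pytest.approx(getattr(rec0, p), abs=2.0)
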