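"""Baseline correction, phosphate fitting and compositional ratios."""

import numpy as np
import pytest

from osteoquant import raman, synthetic
from osteoquant.exceptions import ParameterError, UndefinedRatioError


def _grid(step=1.0):
    return np.arange(300.0, 1801.0, step)


class TestBaseline:
    def test_flat_zero_spectrum_unchanged(self):
        w = _grid()
        spec = raman.RamanSpectrum(w, np.zeros_like(w))
        out = raman.baseline_correct(spec)
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_linear_ramp_with_end_anchors_zeroes_out(self):
        w = _grid()
        spec = raman.RamanSpectrum(w, 3.0 * w + 100.0)
        out = raman.baseline_correct(spec, anchors=(w[0], w[-1]))
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_anchor_outside_range_is_an_error(self):
        w = _grid()
        spec = raman.RamanSpectrum(w, np.zeros_like(w))
        with pytest.raises(ParameterError):
            raman.baseline_correct(spec, anchors=(100.0, 1750.0))

    def test_known_baseline_round_trip_preserves_band_areas(self):
        spec, truth = synthetic.generate_spectrum(
            synthetic.SpectrumParams(baseline_coeffs=(80.0, 0.05, -1e-5))
        )
        corrected = raman.baseline_correct(spec)
        areas = raman.band_areas(corrected)
        for name, want in truth["areas"].items():
            assert areas[name] == pytest.approx(want, rel=0.01), name


class TestPhosphateFit:
    def test_fwhm_recovery_gives_crystallinity_0p054(self):
        spec, _ = synthetic.generate_spectrum(synthetic.SpectrumParams())
        corrected = raman.baseline_correct(spec)
        fit = raman.fit_phosphate_peak(corrected)
        assert fit.ok
        assert fit.fwhm == pytest.approx(18.52, rel=1e-3)
        assert 1.0 / fit.fwhm == pytest.approx(0.054, abs=5e-4)

    def test_amplitude_doubling_doubles_area_not_fwhm(self):
        p1 = synthetic.SpectrumParams(
            bands=[(958.0, 1000.0, 18.52)], baseline_coeffs=(0.0,)
        )
        p2 = synthetic.SpectrumParams(
            bands=[(958.0, 2000.0, 18.52)], baseline_coeffs=(0.0,)
        )
        f1 = raman.fit_phosphate_peak(synthetic.generate_spectrum(p1)[0])
        f2 = raman.fit_phosphate_peak(synthetic.generate_spectrum(p2)[0])
        assert f2.area == pytest.approx(2.0 * f1.area, rel=1e-6)
        assert f2.fwhm == pytest.approx(f1.fwhm, rel=1e-6)

    def test_contaminant_outside_window_leaves_fit_unchanged(self):
        base = synthetic.SpectrumParams(
            bands=[(958.0, 1000.0, 18.52)], baseline_coeffs=(0.0,)
        )
        with_contaminant = synthetic.SpectrumParams(
            bands=[(958.0, 1000.0, 18.52), (1030.0, 400.0, 12.0)],
            baseline_coeffs=(0.0,),
        )
        f1 = raman.fit_phosphate_peak(synthetic.generate_spectrum(base)[0])
        f2 = raman.fit_phosphate_peak(
            synthetic.generate_spectrum(with_contaminant)[0]
        )
        assert f2.area == pytest.approx(f1.area, rel=5e-3)
        assert f2.fwhm == pytest.approx(f1.fwhm, rel=5e-3)


class TestBandAreas:
    def test_zero_spectrum_gives_zero_areas(self):
        w = _grid()
        areas = raman.band_areas(raman.RamanSpectrum(w, np.zeros_like(w)))
        assert all(v == 0.0 for v in areas.values())

    def test_unit_rectangle_of_width_10_has_area_10(self):
        w = _grid(step=0.1)
        y = np.where((w >= 945.0) & (w <= 955.0), 1.0, 0.0)
        areas = raman.band_areas(raman.RamanSpectrum(w, y))
        assert areas["phosphate"] == pytest.approx(10.0, rel=0.02)

    def test_gaussian_integration_matches_closed_form_within_1_percent(self):
        spec, truth = synthetic.generate_spectrum(
            synthetic.SpectrumParams(baseline_coeffs=(0.0,))
        )
        areas = raman.band_areas(spec)
        for name, want in truth["areas"].items():
            assert areas[name] == pytest.approx(want, rel=0.01), name

    def test_window_outside_range_is_an_error(self):
        w = _grid()
        spec = raman.RamanSpectrum(w, np.zeros_like(w))
        with pytest.raises(ParameterError):
            raman.band_areas(spec, {"x": (100.0, 200.0)})


class TestRatios:
    def test_equal_areas_give_unit_mineral_to_matrix(self):
        res = raman.composition_ratios(
            {"phosphate": 5.0, "carbonate": 1.0, "amide_i": 5.0}, 18.0
        )
        assert res.mineral_to_matrix == 1.0
        assert res.carbonate_substitution == pytest.approx(0.2)
        assert res.crystallinity == pytest.approx(1.0 / 18.0)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            raman.composition_ratios(
                {"phosphate": 0.0, "carbonate": 1.0, "amide_i": 5.0}, 18.0
            )

    def test_intensity_scaling_leaves_ratios_unchanged(self):
        spec, _ = synthetic.generate_spectrum(synthetic.spectrum_params_for_ratios())
        r1 = raman.analyze_spectrum(spec)
        scaled = raman.RamanSpectrum(spec.wavenumber, spec.intensity * 7.3)
        r2 = raman.analyze_spectrum(scaled)
        assert r2.mineral_to_matrix == pytest.approx(r1.mineral_to_matrix, rel=1e-9)
        assert r2.carbonate_substitution == pytest.approx(
            r1.carbonate_substitution, rel=1e-9
        )
        assert r2.crystallinity == pytest.approx(r1.crystallinity, rel=1e-9)

    def test_target_ratios_recovered_within_2_percent(self):
        spec, truth = synthetic.generate_spectrum(
            synthetic.spectrum_params_for_ratios(
                mineral_to_matrix=2.539, carbonate_substitution=0.618,
                crystallinity=0.054,
            )
        )
        res = raman.analyze_spectrum(spec)
        assert res.mineral_to_matrix == pytest.approx(2.539, rel=0.02)
        assert res.carbonate_substitution == pytest.approx(0.618, rel=0.02)
        assert res.crystallinity == pytest.approx(0.054, rel=0.01)

    def test_site_aggregation_is_arithmetic_mean(self):
        specs = [
            synthetic.generate_spectrum(
                synthetic.spectrum_params_for_ratios(noise_sd=3.0, seed=s)
            )[0]
            for s in range(3)
        ]
        results = [raman.analyze_spectrum(s) for s in specs]
        agg = raman.aggregate_composition(results)
        assert agg.mineral_to_matrix == pytest.approx(
            np.mean([r.mineral_to_matrix for r in results])
        )
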