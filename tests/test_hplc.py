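"""Peak integration, calibration and crosslink quantitation."""

import numpy as np
import pytest

from osteoquant import hplc, synthetic
from osteoquant.exceptions import (
    CalibrationError,
    InvalidRunError,
    ParameterError,
    UndefinedRatioError,
)


def _flat(level=5.0):
    t = np.arange(0.0, 35.0, 0.01)
    return hplc.Chromatogram(t, np.full_like(t, level))


def _gaussian_chrom(rt=15.0, area=120.0, width=0.1, level=5.0):
    t = np.arange(0.0, 35.0, 0.01)
    y = level + area / (width * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - rt) / width) ** 2
    )
    return hplc.Chromatogram(t, y)


class TestIntegration:
    def test_flat_baseline_window_has_zero_area(self):
        assert hplc.integrate_peak(_flat(), (10.0, 12.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_gaussian_area_matches_closed_form_within_1_percent(self):
        chrom = _gaussian_chrom(area=120.0)
        got = hplc.integrate_peak(chrom, (14.0, 16.0))
        assert got == pytest.approx(120.0, rel=0.01)

    def test_constant_offset_invariance(self):
        c1 = _gaussian_chrom(level=5.0)
        c2 = hplc.Chromatogram(c1.retention_time, c1.signal + 250.0)
        a1 = hplc.integrate_peak(c1, (14.0, 16.0))
        a2 = hplc.integrate_peak(c2, (14.0, 16.0))
        assert a2 == pytest.approx(a1, rel=1e-6)

    def test_window_outside_run_is_an_error(self):
        with pytest.raises(ParameterError):
            hplc.integrate_peak(_flat(), (30.0, 40.0))


def _standard_set(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return synthetic._hplc_standard_set(rng, "fluorescence")


class TestCalibration:
    def test_perfect_standards_have_r2_one_and_exact_slope(self):
        std = _standard_set()
        cal = hplc.build_calibration(
            std["standards"]["pyd"], std["windows"]["pyd"],
            std["windows"]["pyridoxine"], analyte="pyd",
        )
        assert cal.r_squared == pytest.approx(1.0, abs=1e-6)
        # slope = analyte response factor / (IS amount * IS response factor)
        rf = std["analytes"]["pyd"][2]
        is_amount, is_rf = std["internal"][2], std["internal"][3]
        assert cal.slope == pytest.approx(rf / (is_amount * is_rf), rel=0.01)

    def test_too_few_standards_is_an_error(self):
        std = _standard_set()
        with pytest.raises(ParameterError):
            hplc.build_calibration(
                std["standards"]["pyd"][:2], std["windows"]["pyd"],
                std["windows"]["pyridoxine"],
            )

    def test_nonlinear_response_is_rejected(self):
        std = _standard_set()
        pairs = std["standards"]["pyd"]
        # scramble the amounts so ratio vs amount is badly non-linear
        amounts = [a for a, _ in pairs]
        scrambled = [
            (amounts[(i + 2) % len(amounts)], c)
            for i, (_a, c) in enumerate(pairs)
        ]
        with pytest.raises(CalibrationError):
            hplc.build_calibration(
                scrambled, std["windows"]["pyd"], std["windows"]["pyridoxine"],
            )


class TestQuantitation:
    def test_sample_identical_to_standard_returns_its_amount(self):
        std = _standard_set()
        cal = hplc.build_calibration(
            std["standards"]["pyd"], std["windows"]["pyd"],
            std["windows"]["pyridoxine"],
        )
        amount, chrom = std["standards"]["pyd"][2]
        got = hplc.quantify_analyte(
            chrom, cal, std["windows"]["pyd"], std["windows"]["pyridoxine"]
        )
        assert got == pytest.approx(amount, rel=1e-3)

    def test_missing_internal_standard_is_invalid_run(self):
        std = _standard_set()
        cal = hplc.build_calibration(
            std["standards"]["pyd"], std["windows"]["pyd"],
            std["windows"]["pyridoxine"],
        )
        with pytest.raises(InvalidRunError):
            hplc.quantify_analyte(
                _flat(), cal, std["windows"]["pyd"],
                std["windows"]["pyridoxine"],
            )

    def test_zero_amount_sample_quantifies_to_zero(self):
        std = _standard_set()
        cal = hplc.build_calibration(
            std["standards"]["pyd"], std["windows"]["pyd"],
            std["windows"]["pyridoxine"],
        )
        chrom, _ = synthetic.generate_chromatogram(synthetic.ChromatogramParams(
            peaks={"pyd": (18.0, 0.0, 5e9, 0.10)},
            internal_standard=std["internal"],
            noise_sd=1.0, seed=4,
        ))
        got = hplc.quantify_analyte(
            chrom, cal, std["windows"]["pyd"], std["windows"]["pyridoxine"]
        )
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_detector_gain_invariance(self):
        std = _standard_set()
        cal = hplc.build_calibration(
            std["standards"]["pyd"], std["windows"]["pyd"],
            std["windows"]["pyridoxine"],
        )
        amount, chrom = std["standards"]["pyd"][1]
        gained = hplc.Chromatogram(chrom.retention_time, chrom.signal * 3.7)
        got = hplc.quantify_analyte(
            gained, cal, std["windows"]["pyd"], std["windows"]["pyridoxine"]
        )
        assert got == pytest.approx(amount, rel=1e-3)


class TestCollagen:
    def test_zero_mass_gives_zero_mol(self):
        assert hplc.collagen_from_hydroxyproline(0.0) == 0.0

    def test_13p33_ug_gives_3p33_nmol(self):
        assert hplc.collagen_from_hydroxyproline(13.33e-6) == pytest.approx(
            3.3325e-9, rel=1e-9
        )

    def test_linearity(self):
        one = hplc.collagen_from_hydroxyproline(1e-3)
        assert hplc.collagen_from_hydroxyproline(2e-3) == pytest.approx(2 * one)

    def test_negative_mass_is_an_error(self):
        with pytest.raises(ParameterError):
            hplc.collagen_from_hydroxyproline(-1.0)


class TestRatios:
    def test_equal_moles_give_unit_ratio(self):
        res = hplc.crosslink_ratios(
            {"pyd": 2e-7, "dpd": 2e-7, "pe": 2e-7}, 2e-7
        )
        assert res.pyd_per_collagen == pytest.approx(1.0)

    def test_zero_collagen_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            hplc.crosslink_ratios({"pyd": 1.0}, 0.0)

    def test_end_to_end_within_3_percent_at_2_percent_noise(self):
        std = _standard_set()
        hyp = 1.3e-3
        col = hplc.collagen_from_hydroxyproline(hyp)
        want = {"pyd": 0.60, "dpd": 0.37, "pe": 878.0}
        fa = std["analytes"]
        peaks = {
            name: (fa[name][0], want[name] * col, fa[name][2], fa[name][3])
            for name in want
        }
        # 2 % signal noise, referenced to the smallest analyte peak's mean
        # in-window height (area / window width)
        noise = 0.02 * min(
            amount * rf / (10.0 * width)
            for _rt, amount, rf, width in peaks.values()
        )
        chrom, _ = synthetic.generate_chromatogram(synthetic.ChromatogramParams(
            peaks=peaks, internal_standard=std["internal"],
            noise_sd=noise, seed=9,
        ))
        for name, target in want.items():
            cal = hplc.build_calibration(
                std["standards"][name], std["windows"][name],
                std["windows"]["pyridoxine"], analyte=name,
            )
            amt = hplc.quantify_analyte(
                chrom, cal, std["windows"][name], std["windows"]["pyridoxine"]
            )
            assert amt / col == pytest.approx(target, rel=0.03), name
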