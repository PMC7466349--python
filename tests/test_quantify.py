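"""Internal-standard integration, concentration formula, S/N, detection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from arsqnmr import SampleSpec, make_sample
from arsqnmr.errors import (
    InternalStandardError,
    ValidationError,
    WindowOverlapError,
)
from arsqnmr.nmr_processing import fourier_transform, zero_fill, apodize
from arsqnmr.pipeline import analyze_sample, process_fid, simulate_sample
from arsqnmr.quantify import (
    ARS_WINDOW,
    IS_WINDOW,
    IntegrationWindow,
    concentration,
    detection_call,
    integrate,
    quantify_spectrum,
    round_mg_per_kg,
    round_mmol_per_kg,
    snr,
    to_mg_per_kg,
)
from arsqnmr.spin_sim import ars_resonance, is_resonance, synthesize_fid

# Published concentration table rows whose mg/Kg and mmol/Kg columns agree
# under the 390 g/mol average molecular weight (two inconsistent rows are
# excluded and tracked in the preset metadata).
CONSISTENT_ROWS = [
    (638, 1.64), (574, 1.47), (510, 1.31), (191, 0.49), (63, 0.16),
    (925, 2.37), (255, 0.65), (455, 1.17), (1090, 2.79), (351, 0.90),
    (330, 0.85), (1084, 2.78),
]


class TestIntegrate:
    def test_three_proton_singlet_against_one_proton_standard(self):
        """An analyte amount 0.2004x the standard (5.41e-4 vs 2.70e-3 mmol)
        carries three protons per molecule, so its normalised integral is
        3 x 0.2004 ~ 0.601 (matched T1 so saturation cancels)."""
        t1 = 2.0
        fid = synthesize_fid([ars_resonance(0.2004 * 2.70e-3, t1=t1),
                              is_resonance(2.70e-3, t1=t1)],
                             noise_sigma=0.0)
        spec = fourier_transform(zero_fill(apodize(fid, 0.3), 2))
        areas = integrate(spec)
        assert areas["IS"] == 1.0
        assert areas["ARS"] == pytest.approx(0.601, rel=0.01)

    def test_missing_internal_standard_rejected(self):
        fid = synthesize_fid([ars_resonance(1.8e-4)], noise_sigma=0.0)
        spec = fourier_transform(apodize(fid, 0.3))
        with pytest.raises(InternalStandardError):
            integrate(spec)

    def test_overlapping_windows_rejected(self, clean_spectrum):
        with pytest.raises(WindowOverlapError):
            integrate(clean_spectrum,
                      [IntegrationWindow(6.0, 0.2, "ARS"),
                       IntegrationWindow(6.1, 0.2, "IS")])

    def test_adversarial_matrix_peak_stays_outside_window(self):
        """A matrix line at 6.3 ppm, just past the window edge, moves the
        normalised ARS integral by <0.5%."""
        plain = analyze_sample(SampleSpec("x", 638.0, seed=1),
                               noise_sigma=0.0)
        spiked = analyze_sample(make_sample("adversarial", seed=1),
                                noise_sigma=0.0)
        assert spiked.i_ars == pytest.approx(plain.i_ars, rel=5e-3)


class TestConcentration:
    def test_published_formula_monococcum_flour(self):
        _, c_kg = concentration(0.601, 0.00270, 330.0)
        assert round_mmol_per_kg(c_kg) == 1.64

    def test_zero_integral_gives_zero(self):
        assert concentration(0.0)[1] == 0.0

    def test_inverse_linear_in_sample_mass(self):
        full = concentration(0.601, 0.00270, 330.0)[1]
        half = concentration(0.601, 0.00270, 660.0)[1]
        assert half == pytest.approx(full / 2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            concentration(0.5, is_mmol=0.0)
        with pytest.raises(ValidationError):
            concentration(0.5, sample_mass=0.0)
        with pytest.raises(ValidationError):
            concentration(-0.1)

    @given(i=st.floats(0.0, 10.0), scale=st.floats(0.1, 10.0))
    def test_linear_in_integral_and_standard_amount(self, i, scale):
        base = concentration(i, 0.0027, 330.0)[1]
        assert concentration(i * scale, 0.0027, 330.0)[1] == \
            pytest.approx(base * scale, rel=1e-12, abs=1e-12)
        assert concentration(i, 0.0027 * scale, 330.0)[1] == \
            pytest.approx(base * scale, rel=1e-12, abs=1e-12)


class TestUnitConversion:
    @pytest.mark.parametrize("mg,mmol", CONSISTENT_ROWS)
    def test_published_rows_convert_consistently(self, mg, mmol):
        assert round_mmol_per_kg(mg / 390.0) == mmol

    def test_mass_molar_ratio_is_mw(self):
        assert to_mg_per_kg(1.17) == pytest.approx(1.17 * 390.0)
        assert to_mg_per_kg(0.0) == 0.0

    def test_report_rounding_conventions(self):
        assert round_mg_per_kg(455.4) == 455
        assert round_mmol_per_kg(1.16677) == 1.17


class TestSnr:
    def test_noise_free_reports_infinity(self, clean_spectrum):
        assert math.isinf(snr(clean_spectrum))

    def test_reproducible_for_fixed_seed(self, monococcum_sample):
        a = analyze_sample(monococcum_sample, seed=11).snr
        b = analyze_sample(monococcum_sample, seed=11).snr
        assert a == b

    def test_overlapping_noise_window_rejected(self, clean_spectrum):
        with pytest.raises(WindowOverlapError):
            snr(clean_spectrum, ARS_WINDOW, noise_window=(6.05, 5.95))

    def test_snr_linear_in_amount(self):
        """Doubling the analyte amount doubles S/N within 10% (20 seeds)."""
        lo = SampleSpec("x", 200.0, seed=0)
        hi = SampleSpec("x", 400.0, seed=0)
        r = []
        for k in range(20):
            s_lo = analyze_sample(lo, seed=k).snr
            s_hi = analyze_sample(hi, seed=1000 + k).snr
            r.append(s_hi / s_lo)
        assert np.mean(r) == pytest.approx(2.0, rel=0.10)


class TestDetectionCall:
    @pytest.mark.parametrize("snr_value,status", [
        (2.9, "nd"),
        (3.0, "below_loq"),      # boundaries belong to the higher category
        (9.9, "below_loq"),
        (10.0, "quantified"),
        (math.inf, "quantified"),
    ])
    def test_thresholds(self, snr_value, status):
        assert detection_call(100.0, snr_value) == status

    def test_negative_snr_rejected(self):
        with pytest.raises(ValidationError):
            detection_call(100.0, -1.0)


class TestQuantifySpectrum:
    def test_mass_molar_consistency(self, noisy_spectrum):
        res = quantify_spectrum(noisy_spectrum)
        assert res.c_mg_per_kg == pytest.approx(res.c_mmol_per_kg * 390.0)

    def test_report_row_prints_nd_for_non_detections(self):
        res = analyze_sample(make_sample("t_aestivum_white", seed=5), seed=5)
        row = res.report_row()
        assert res.status == "nd"
        assert row["c_mg_per_kg"] == "ND" and row["c_mmol_per_kg"] == "ND"
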