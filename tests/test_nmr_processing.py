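"""Processing chain: apodization, zero-fill, FT, phasing, baseline, axis."""

import numpy as np
import pytest

from arsqnmr import SampleSpec
from arsqnmr.errors import (
    EmptyFIDError,
    PeakNotFoundError,
    ValidationError,
    WindowOverlapError,
)
from arsqnmr.nmr_processing import (
    PhaseParams,
    Spectrum,
    apodize,
    autophase,
    baseline_correct,
    calibrate_ppm,
    fourier_transform,
    phase,
    zero_fill,
)
from arsqnmr.pipeline import simulate_sample
from arsqnmr.spin_sim import (
    FID,
    Resonance,
    ars_resonance,
    is_resonance,
    synthesize_fid,
)
from conftest import interpolated_fwhm_hz


@pytest.fixture(scope="module")
def single_line_fid():
    """One noise-free 1 Hz-wide singlet at 6.00 ppm."""
    return synthesize_fid([ars_resonance(1e-3)], noise_sigma=0.0)


@pytest.fixture(scope="module")
def two_line_fid():
    return synthesize_fid([ars_resonance(2e-4), is_resonance(27e-4)],
                          noise_sigma=0.0)


class TestApodize:
    def test_zero_broadening_is_identity(self, single_line_fid):
        out = apodize(single_line_fid, 0.0)
        assert np.array_equal(out.data, single_line_fid.data)

    def test_fwhm_grows_by_line_broadening(self, single_line_fid):
        spec = fourier_transform(zero_fill(apodize(single_line_fid, 0.3), 8))
        assert interpolated_fwhm_hz(spec) == pytest.approx(1.3, rel=0.05)

    def test_peak_area_invariant(self, single_line_fid):
        # wide window so the comparison measures area, not tail truncation
        w = (7.0, 5.0)
        a0 = fourier_transform(apodize(single_line_fid, 0.0)).integral(w)
        a3 = fourier_transform(apodize(single_line_fid, 0.3)).integral(w)
        assert a3 == pytest.approx(a0, rel=1e-3)

    def test_negative_broadening_rejected(self, single_line_fid):
        with pytest.raises(ValidationError):
            apodize(single_line_fid, -0.1)


class TestZeroFill:
    def test_factor_one_keeps_data(self, single_line_fid):
        assert np.array_equal(zero_fill(single_line_fid, 1).data,
                              single_line_fid.data)

    def test_factor_two_doubles_complex_points(self, single_line_fid):
        assert zero_fill(single_line_fid, 2).data.size == 2 * 16384

    def test_area_preserved(self, single_line_fid):
        w = (7.0, 5.0)
        a1 = fourier_transform(zero_fill(single_line_fid, 1)).integral(w)
        a2 = fourier_transform(zero_fill(single_line_fid, 2)).integral(w)
        assert a2 == pytest.approx(a1, rel=1e-3)

    def test_non_power_of_two_rejected(self, single_line_fid):
        with pytest.raises(ValidationError):
            zero_fill(single_line_fid, 3)


class TestFourierTransform:
    def test_peak_lands_on_chemical_shift(self, single_line_fid):
        spec = fourier_transform(single_line_fid)
        peak_ppm = spec.ppm[int(np.argmax(spec.real))]
        step = spec.params.sweep_ppm / spec.ppm.size
        assert abs(peak_ppm - 6.00) <= step

    def test_height_ratio_follows_amount_and_saturation(self, two_line_fid):
        from arsqnmr.spin_sim import saturation_factor
        # zero-fill so the discrete maxima sample both line centres fairly
        spec = fourier_transform(zero_fill(two_line_fid, 8))
        h_ars = spec.real[spec.window((6.1, 5.9))].max()
        h_is = spec.real[spec.window((9.89, 9.69))].max()
        expected = (3 * 2e-4 * saturation_factor(1.2, 10.0, 3.11)) / \
            (1 * 27e-4 * saturation_factor(2.5, 10.0, 3.11))
        assert h_ars / h_is == pytest.approx(expected, rel=0.01)

    def test_zero_fid_gives_zero_spectrum(self, default_params):
        fid = FID(np.zeros(default_params.n_complex, complex), default_params)
        spec = fourier_transform(fid)
        assert not spec.real.any() and not spec.imag.any()

    def test_wrong_length_fid_rejected(self, default_params):
        with pytest.raises(ValidationError):
            FID(np.zeros(10, complex), default_params)

    def test_digital_resolution_matches_acquisition_time(self,
                                                         single_line_fid):
        spec = fourier_transform(single_line_fid)
        assert spec.digital_resolution == \
            pytest.approx(1.0 / 3.11, rel=0.01)

    def test_ppm_axis_descending(self, single_line_fid):
        spec = fourier_transform(single_line_fid)
        assert np.all(np.diff(spec.ppm) < 0)


class TestPhase:
    def test_zero_params_identity(self, clean_spectrum):
        out = phase(clean_spectrum, PhaseParams(0.0, 0.0))
        assert np.allclose(out.real, clean_spectrum.real)

    def test_autophase_recovers_injected_zero_order(self, clean_spectrum):
        rotated = phase(clean_spectrum, PhaseParams(30.0, 0.0))
        params, converged = autophase(rotated)
        assert converged
        assert params.zero_order == pytest.approx(-30.0, abs=1.0)

    def test_autophase_restores_window_integral(self, clean_spectrum):
        w = (6.1, 5.9)
        reference = clean_spectrum.integral(w)
        rotated = phase(clean_spectrum, PhaseParams(30.0, 0.0))
        assert rotated.integral(w) < reference   # misphasing loses area
        restored = phase(rotated, "auto")
        assert restored.integral(w) == pytest.approx(reference, rel=5e-3)

    def test_manual_override_applied_exactly(self, clean_spectrum):
        out = phase(clean_spectrum, PhaseParams(90.0, 0.0))
        comp_in = clean_spectrum.real + 1j * clean_spectrum.imag
        comp_out = out.real + 1j * out.imag
        assert np.allclose(comp_out, comp_in * np.exp(-1j * np.pi / 2))

    def test_unknown_mode_rejected(self, clean_spectrum):
        with pytest.raises(ValidationError):
            phase(clean_spectrum, "magic")


class TestBaseline:
    def test_flat_baseline_untouched(self, clean_spectrum):
        out = baseline_correct(clean_spectrum)
        scale = np.max(np.abs(clean_spectrum.real))
        assert np.max(np.abs(out.real - clean_spectrum.real)) < 1e-3 * scale

    def test_linear_tilt_removed(self, clean_spectrum):
        w = (6.1, 5.9)
        reference = clean_spectrum.integral(w)
        tilt = 0.05 * np.max(clean_spectrum.real) * \
            (clean_spectrum.ppm - 6.5) / 13.0
        tilted = Spectrum(clean_spectrum.real + tilt, clean_spectrum.imag,
                          clean_spectrum.ppm, clean_spectrum.params,
                          clean_spectrum.processing_log)
        fixed = baseline_correct(tilted)
        assert fixed.integral(w) == pytest.approx(reference, rel=0.01)

    def test_degree_zero_removes_constant_offset(self, default_params):
        # flat signal-free trace with a pure constant offset
        n = 4096
        ppm = np.linspace(13.0, 0.0, n)
        offset = 3.21
        flat = Spectrum(np.full(n, offset), np.zeros(n), ppm, default_params,
                        ({"step": "fourier_transform"},))
        fixed = baseline_correct(flat, degree=0)
        assert np.max(np.abs(fixed.real)) == pytest.approx(0.0, abs=1e-9)

    def test_anchor_overlapping_integration_window_rejected(self,
                                                            clean_spectrum):
        with pytest.raises(WindowOverlapError):
            baseline_correct(clean_spectrum, anchors=[(6.05, 5.95)])

    def test_als_method_runs(self, noisy_spectrum):
        out = baseline_correct(noisy_spectrum, method="als")
        assert out.processing_log[-1]["method"] == "als"


class TestCalibrate:
    def test_correct_axis_shifts_by_zero(self, clean_spectrum):
        out = calibrate_ppm(clean_spectrum)
        step = clean_spectrum.params.sweep_ppm / clean_spectrum.ppm.size
        assert abs(out.processing_log[-1]["offset_ppm"]) <= step

    def test_injected_offset_corrected(self, clean_spectrum):
        shifted = Spectrum(clean_spectrum.real, clean_spectrum.imag,
                           clean_spectrum.ppm + 0.05, clean_spectrum.params,
                           clean_spectrum.processing_log)
        out = calibrate_ppm(shifted)
        step = clean_spectrum.params.sweep_ppm / clean_spectrum.ppm.size
        assert out.processing_log[-1]["offset_ppm"] == \
            pytest.approx(-0.05, abs=step)

    def test_signal_free_window_rejected(self, clean_spectrum):
        with pytest.raises(PeakNotFoundError):
            calibrate_ppm(clean_spectrum, reference_shift=11.0,
                          search_window=(11.2, 10.8))


class TestProvenance:
    def test_each_step_appends_one_log_entry(self, monococcum_sample):
        fid = simulate_sample(monococcum_sample, noise_sigma=0.0)
        assert fid.processing_log == ()
        fid = apodize(fid, 0.3)
        assert len(fid.processing_log) == 1
        fid = zero_fill(fid, 2)
        assert len(fid.processing_log) == 2
        spec = fourier_transform(fid)
        assert len(spec.processing_log) == 3
        spec = phase(spec, "auto")
        assert len(spec.processing_log) == 4
        spec = baseline_correct(spec)
        assert len(spec.processing_log) == 5
        spec = calibrate_ppm(spec)
        assert len(spec.processing_log) == 6
        assert [e["step"] for e in spec.processing_log] == [
            "apodize", "zero_fill", "fourier_transform", "phase",
            "baseline_correct", "calibrate_ppm"]

    def test_chain_preserves_analytic_peak_area(self):
        """Window integral after the full chain matches the analytic
        Lorentzian area (amplitude / spectrometer frequency in ppm units)
        within 1%."""
        from arsqnmr.spin_sim import saturation_factor
        amount, t1 = 1e-3, 1.2
        fid = synthesize_fid([Resonance(6.0, 3, amount, t1=t1)],
                             noise_sigma=0.0)
        spec = fourier_transform(zero_fill(apodize(fid, 0.3), 2))
        spec = baseline_correct(phase(spec, PhaseParams(0.0, 0.0)))
        # discrete-transform area: amplitude x sweep(ppm) / 2
        amp = 16 * 3 * amount * saturation_factor(t1, 10.0, 3.11)
        analytic = amp * spec.params.sweep_ppm / 2.0
        assert spec.integral((7.0, 5.0)) == pytest.approx(analytic, rel=0.01)
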