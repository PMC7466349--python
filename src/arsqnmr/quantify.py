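"""Internal-standard quantification of the 6.00 ppm alkylresorcinol singlet.

The 9.79 ppm syringaldehyde aldehyde integral is set to 1; the normalised
alkylresorcinol integral I_ARS is divided by 3 (three aromatic protons) and
scaled by the moles of internal standard per sample mass:

    C [mmol/mg] = (I_ARS / 3) * mmol_IS / M_sample

with mmol_IS = 0.00270 (0.5 mg syringaldehyde, printed constant) and
M_sample = 330 mg by default.  Mass concentrations use the C19/C21 average
molecular weight, 390 g/mol.  Detection status follows the signal-to-noise
thresholds S/N >= 10 (quantified) and S/N >= 3 (detected, below LOQ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .errors import InternalStandardError, ValidationError, WindowOverlapError
from .nmr_processing import Spectrum, windows_overlap

__all__ = [
    "IntegrationWindow",
    "QuantResult",
    "ARS_WINDOW",
    "IS_WINDOW",
    "integrate",
    "concentration",
    "to_mg_per_kg",
    "snr",
    "detection_call",
    "quantify_spectrum",
    "round_mg_per_kg",
    "round_mmol_per_kg",
]


@dataclass(frozen=True)
class IntegrationWindow:
    center: float                       # ppm
    half_width: float = c.WINDOW_HALF_WIDTH_PPM
    label: str = ""

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValidationError("half_width must be positive")

    @property
    def bounds(self) -> tuple[float, float]:
        """(high, low) ppm bounds."""
        return (self.center + self.half_width, self.center - self.half_width)


ARS_WINDOW = IntegrationWindow(c.ARS_SHIFT_PPM, label="ARS")
IS_WINDOW = IntegrationWindow(c.IS_SHIFT_PPM, label="IS")


@dataclass(frozen=True)
class QuantResult:
    """One quantified sample."""

    i_ars: float                  # normalised integral (IS = 1)
    c_mmol_per_kg: float
    c_mg_per_kg: float
    snr: float
    status: str                   # quantified | below_loq | nd
    is_mmol: float = c.IS_MMOL_PRINTED
    sample_mass: float = c.SAMPLE_MASS_MG   # mg
    mw_avg: float = c.MW_AVG
    sample_name: str = field(default="", compare=False)

    def report_row(self) -> dict:
        """Table-style row with the published rounding conventions
        (mg/Kg to the nearest integer, mmol/Kg to two decimals, ND for
        non-detections)."""
        nd = self.status == "nd"
        return {
            "sample": self.sample_name,
            "i_ars": round(self.i_ars, 4),
            "snr": math.inf if math.isinf(self.snr) else round(self.snr, 1),
            "c_mg_per_kg": "ND" if nd else round_mg_per_kg(self.c_mg_per_kg),
            "c_mmol_per_kg": "ND" if nd else round_mmol_per_kg(self.c_mmol_per_kg),
            "status": self.status,
        }


def integrate(spec: Spectrum,
              windows: list[IntegrationWindow] | None = None,
              is_label: str = "IS",
              noise_window: tuple[float, float] = c.NOISE_WINDOW,
              ) -> dict[str, float]:
    """Trapezoidal window integrals on the real trace, normalised so the
    internal-standard window equals 1.

    Raises :class:`InternalStandardError` when the IS integral is
    non-positive or does not clear three times the noise-equivalent
    integral — quantification is impossible without the reference.
    """
    windows = windows or [ARS_WINDOW, IS_WINDOW]
    labels = [w.label for w in windows]
    if is_label not in labels:
        raise ValidationError(f"no window labelled {is_label!r}")
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if windows_overlap(a.bounds, b.bounds):
                raise WindowOverlapError(
                    f"integration windows {a.label!r} and {b.label!r} overlap")

    areas = {w.label: spec.integral(w.bounds) for w in windows}
    is_area = areas[is_label]
    if is_area <= 0.0:
        raise InternalStandardError(
            f"internal-standard integral is {is_area:.3g} (must be > 0)")
    is_win = next(w for w in windows if w.label == is_label)
    is_height = float(spec.real[spec.window(is_win.bounds)].max())
    # the reference peak must stand clear of both the noise floor and the
    # far tails of other lines (guards against an IS-free acquisition)
    if is_height < 1e-4 * float(np.max(spec.real)):
        raise InternalStandardError(
            "no internal-standard peak in the reference window (height "
            f"{is_height:.3g} is negligible against the spectrum maximum)")
    noise = spec.noise_rms(noise_window)
    if noise > 0.0:
        noise_equiv = noise * 2.0 * is_win.half_width
        if is_area < 3.0 * noise_equiv:
            raise InternalStandardError(
                "internal-standard integral below 3x the noise-equivalent "
                f"area ({is_area:.3g} < {3 * noise_equiv:.3g})")
    return {label: a / is_area for label, a in areas.items()}


def concentration(i_ars: float,
                  is_mmol: float = c.IS_MMOL_PRINTED,
                  sample_mass: float = c.SAMPLE_MASS_MG,
                  n_protons: int = c.ARS_N_PROTONS) -> tuple[float, float]:
    """(mmol per mg, mmol per Kg) of total alkylresorcinols.

    ``i_ars`` is the IS-normalised integral of the 3-proton singlet;
    dividing by the proton count converts it to a molar ratio against the
    1-proton internal standard.
    """
    if i_ars < 0:
        raise ValidationError("i_ars must be >= 0")
    if is_mmol <= 0:
        raise ValidationError("is_mmol must be positive")
    if sample_mass <= 0:
        raise ValidationError("sample_mass must be positive")
    c_mmol_per_mg = (i_ars / n_protons) * is_mmol / sample_mass
    return c_mmol_per_mg, c_mmol_per_mg * 1e6


def to_mg_per_kg(c_mmol_per_kg: float, mw_avg: float = c.MW_AVG) -> float:
    """Convert mmol/Kg to mg/Kg via the C19/C21 average molecular weight."""
    if mw_avg <= 0:
        raise ValidationError("mw_avg must be positive")
    return c_mmol_per_kg * mw_avg


def round_mg_per_kg(x: float) -> int:
    return int(round(x))


def round_mmol_per_kg(x: float) -> float:
    return round(x, 2)


def snr(spec: Spectrum,
        peak_window: IntegrationWindow = ARS_WINDOW,
        noise_window: tuple[float, float] = c.NOISE_WINDOW) -> float:
    """Signal-to-noise ratio: peak maximum height over twice the detrended
    RMS of the noise window (common instrument-software convention).

    The noise window is detrended with a straight line so the smooth far
    tails of distant peaks do not masquerade as noise; an effectively
    noise-free spectrum (residual below 1e-6 of the peak, far beyond any
    attainable experimental S/N) reports ``inf``.
    """
    if windows_overlap(peak_window.bounds, noise_window):
        raise WindowOverlapError(
            f"noise window {noise_window} overlaps peak window "
            f"{peak_window.bounds}")
    m = spec.window(peak_window.bounds)
    peak = float(spec.real[m].max()) if m.any() else 0.0
    nm = spec.window(noise_window)
    seg = spec.real[nm]
    if seg.size < 2:
        raise ValidationError("noise window holds too few points")
    x = spec.ppm[nm]
    resid = seg - np.polynomial.Polynomial.fit(x, seg, 1)(x)
    noise = float(np.sqrt(np.mean(resid ** 2)))
    if noise <= 1e-6 * abs(peak):
        return math.inf
    return peak / (2.0 * noise)


def detection_call(c_mg_per_kg: float, snr_value: float,
                   lod_snr: float = c.LOD_SNR,
                   loq_snr: float = c.LOQ_SNR) -> str:
    """Detection status from S/N thresholds (boundaries inclusive upward):
    ``nd`` below S/N 3, ``below_loq`` in [3, 10), ``quantified`` at or above
    10."""
    if snr_value < 0:
        raise ValidationError("snr must be >= 0")
    if snr_value < lod_snr:
        return "nd"
    if snr_value < loq_snr:
        return "below_loq"
    return "quantified"


def quantify_spectrum(spec: Spectrum,
                      is_mmol: float = c.IS_MMOL_PRINTED,
                      sample_mass: float = c.SAMPLE_MASS_MG,
                      mw_avg: float = c.MW_AVG,
                      windows: list[IntegrationWindow] | None = None,
                      noise_window: tuple[float, float] = c.NOISE_WINDOW,
                      sample_name: str = "") -> QuantResult:
    """Full quantification of a processed spectrum: integrate, normalise to
    the internal standard, convert to concentrations and call detection."""
    windows = windows or [ARS_WINDOW, IS_WINDOW]
    ars_win = next(w for w in windows if w.label == "ARS")
    normalised = integrate(spec, windows, noise_window=noise_window)
    i_ars = max(normalised["ARS"], 0.0)
    _, c_mmol_per_kg = concentration(i_ars, is_mmol, sample_mass)
    c_mg = to_mg_per_kg(c_mmol_per_kg, mw_avg)
    s = snr(spec, ars_win, noise_window)
    status = detection_call(c_mg, s)
    return QuantResult(i_ars=i_ars, c_mmol_per_kg=c_mmol_per_kg,
                       c_mg_per_kg=c_mg, snr=s, status=status,
                       is_mmol=is_mmol, sample_mass=sample_mass,
                       mw_avg=mw_avg, sample_name=sample_name)
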